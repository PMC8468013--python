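"""Reading, validating and writing genome inputs.

A "genome" here is the annotated gene complement of one assembly: an ordered
collection of nucleotide CDS/gene sequences plus a species label.  Inputs are
either a per-genome multi-FASTA of gene sequences, or a genome FASTA with a
GFF3 from which CDS features are extracted.  All internal coordinates are
0-based half-open; GFF (1-based inclusive) is converted at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeInputError(ValueError):
    """Raised when a genome input file violates the format contract."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: identifier, upper-case nucleotide sequence.

    ``source_coords`` (contig_id, start, end, strand) is retained when the
    gene was extracted from a genome FASTA + GFF3; start/end are 0-based
    half-open on the forward strand of the contig.
    """

    gene_id: str
    seq: str
    source_coords: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise GenomeInputError("empty gene_id")
        if not self.seq:
            raise GenomeInputError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise GenomeInputError(
                f"gene {self.gene_id!r}: invalid characters {sorted(bad)!r} "
                "(allowed: A,C,G,T,N; U is mapped to T at ingest)"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class GenomeRecord:
    """All genes of one genome, with its species label."""

    genome_id: str
    species_label: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeInputError(
                f"genome {self.genome_id!r}: duplicate gene_id(s) {dup}"
            )

    @property
    def gc_fraction(self) -> float:
        """(G+C)/(A+C+G+T) pooled over all genes; N excluded entirely."""
        gc = at = 0
        for g in self.genes:
            gc += g.seq.count("G") + g.seq.count("C")
            at += g.seq.count("A") + g.seq.count("T")
        if gc + at == 0:
            raise GenomeInputError(
                f"genome {self.genome_id!r}: no unambiguous bases"
            )
        return gc / (gc + at)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class GenomeSet:
    """The full input cohort and the species clade to screen for.

    Species labels are free strings matched exactly (case-sensitive).
    """

    genomes: list[GenomeRecord]
    target_species: str

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            raise GenomeInputError("duplicate genome_id in genome set")
        labels = {g.species_label for g in self.genomes}
        if self.target_species not in labels:
            raise GenomeInputError(
                f"no genome carries target species {self.target_species!r}"
            )
        if labels == {self.target_species}:
            raise GenomeInputError(
                "genome set contains only target-species genomes; "
                "a specificity screen needs non-target genomes"
            )

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def target_genomes(self) -> list[GenomeRecord]:
        return [g for g in self.genomes if g.species_label == self.target_species]

    @property
    def nontarget_genomes(self) -> list[GenomeRecord]:
        return [g for g in self.genomes if g.species_label != self.target_species]

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    @property
    def n_genes(self) -> int:
        return sum(g.n_genes for g in self.genomes)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def compute_gc(seq: str) -> float:
    """GC fraction (G+C)/(A+C+G+T); N ignored in numerator and denominator."""
    if not seq:
        raise GenomeInputError("compute_gc: empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T") + s.count("U")
    if gc + at == 0:
        raise GenomeInputError("compute_gc: sequence has no unambiguous bases")
    return gc / (gc + at)


def _normalize(seq: str, where: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise GenomeInputError(
            f"{where}: invalid characters {sorted(bad)!r}"
        )
    return s


def read_gene_fasta(path: str | os.PathLike, genome_id: str,
                    species_label: str) -> GenomeRecord:
    """Read one genome's gene multi-FASTA.

    The header token before the first whitespace is the gene_id; sequences
    are upper-cased and U→T mapped.  Wrapped and single-line FASTA are
    equivalent.  Empty files, duplicate ids and out-of-alphabet characters
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeInputError(f"no such file: {path}")
    genes: list[GeneRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq), f"{path.name}:{rec.id}")
        genes.append(GeneRecord(gene_id=rec.id, seq=seq))
    if not genes:
        raise GenomeInputError(f"{path}: no FASTA records")
    return GenomeRecord(genome_id=genome_id, species_label=species_label,
                        genes=genes)


def extract_cds_from_gff(genome_fasta: str | os.PathLike,
                         gff_path: str | os.PathLike,
                         genome_id: str, species_label: str) -> GenomeRecord:
    """Extract CDS features from a genome FASTA + GFF3 annotation.

    GFF coordinates are 1-based inclusive; minus-strand CDS are
    reverse-complemented.  gene_id comes from the feature's ID attribute.
    """
    import gffutils

    contigs = {
        rec.id: _normalize(str(rec.seq), f"contig {rec.id}")
        for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    if not contigs:
        raise GenomeInputError(f"{genome_fasta}: no contigs")
    db = gffutils.create_db(str(gff_path), dbfn=":memory:",
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise GenomeInputError(
                f"CDS {feat.id!r}: unknown contig {feat.seqid!r}"
            )
        contig = contigs[feat.seqid]
        start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
        if start0 < 0 or end0 > len(contig) or start0 >= end0:
            raise GenomeInputError(
                f"CDS {feat.id!r}: coordinates {feat.start}..{feat.end} "
                f"outside contig {feat.seqid!r} (length {len(contig)})"
            )
        seq = contig[start0:end0]
        if feat.strand == "-":
            seq = reverse_complement(seq)
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneRecord(gene_id=gene_id, seq=seq,
                                source_coords=(feat.seqid, start0, end0,
                                               feat.strand or "+")))
    if not genes:
        raise GenomeInputError(f"{gff_path}: no CDS features")
    return GenomeRecord(genome_id=genome_id, species_label=species_label,
                        genes=genes)


def read_species_table(path: str | os.PathLike) -> dict[str, str]:
    """Read the 2-column TSV (genome_id, species_label) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise GenomeInputError(f"{path}: species table needs 2 columns")
    if df[0].duplicated().any():
        dups = sorted(df[0][df[0].duplicated()])
        raise GenomeInputError(f"{path}: duplicate genome_id(s) {dups}")
    return dict(zip(df[0], df[1]))


def read_genome_set(gene_fasta_paths: dict[str, str | os.PathLike],
                    species_table: dict[str, str],
                    target_species: str) -> GenomeSet:
    """Assemble a GenomeSet from per-genome gene FASTAs and a label table."""
    genomes = []
    for genome_id in sorted(gene_fasta_paths):
        if genome_id not in species_table:
            raise GenomeInputError(
                f"genome {genome_id!r} missing from species table"
            )
        genomes.append(read_gene_fasta(gene_fasta_paths[genome_id],
                                       genome_id, species_table[genome_id]))
    return GenomeSet(genomes=genomes, target_species=target_species)


def write_gene_fasta(genome: GenomeRecord, path: str | os.PathLike,
                     width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i:i + width] + "\n")


def write_genome_set(genome_set: GenomeSet, outdir: str | os.PathLike) -> None:
    """Write per-genome FASTAs plus the species table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in genome_set.genomes:
        write_gene_fasta(g, outdir / f"{g.genome_id}.fasta")
        rows.append((g.genome_id, g.species_label))
    pd.DataFrame(rows).to_csv(outdir / "species.tsv", sep="\t",
                              header=False, index=False)


def load_genome_set_dir(indir: str | os.PathLike,
                        target_species: str) -> GenomeSet:
    """Inverse of :func:`write_genome_set`."""
    indir = Path(indir)
    table = read_species_table(indir / "species.tsv")
    paths = {gid: indir / f"{gid}.fasta" for gid in table}
    return read_genome_set(paths, table, target_species)
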