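"""Synthetic bacterial communities with full ground truth.

The generator emulates the statistical structure the marker-discovery
analysis assumes: several species clades; core gene families present in
every genome; accessory families present in random multi-species subsets;
one or more *planted* clade-unique marker genes carried by every
target-species genome and by nothing else; and, optionally, a distant
homolog of the marker placed in one non-target species at a prescribed
amino-acid identity (the "36% homolog" situation that a cross-homology
scan must surface but not be confused by).

Divergence parameters are expected *pairwise* nucleotide divergences
between two emitted sequences (each lineage is substituted at half the
stated rate from the shared ancestor).  Substitution-only by default; an
optional indel rate exists to stress the aligner.  No genome architecture
(operons, synteny) is modelled and no sequencing reads are produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustering import GeneKey, translate_cds
from .genome_io import GeneRecord, GenomeRecord, GenomeSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community.

    ``genomes_per_species=None`` gives the default cohort: 5 genomes of the
    target species plus 3 of each other species.
    """

    n_species: int = 9
    genomes_per_species: Optional[dict[str, int]] = None
    n_core_genes: int = 120
    n_accessory_genes: int = 80
    n_planted_markers: int = 1
    gene_length_range: tuple[int, int] = (300, 900)
    within_species_divergence: float = 0.02
    between_species_divergence: float = 0.12
    marker_homolog_identity: Optional[float] = 0.36
    marker_homolog_species: Optional[str] = None  # default: first non-target
    indel_rate: float = 0.0
    gc_target: float = 0.47
    seed: int = 0
    target_species: str = "species_01"

    def species_names(self) -> list[str]:
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]

    def resolved_genomes_per_species(self) -> dict[str, int]:
        if self.genomes_per_species is not None:
            return dict(self.genomes_per_species)
        return {sp: (5 if sp == self.target_species else 3)
                for sp in self.species_names()}

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need ≥2 species")
        if self.n_planted_markers < 1:
            raise ValueError("need ≥1 planted marker")
        if min(self.n_core_genes, self.n_accessory_genes) < 0:
            raise ValueError("gene counts must be ≥ 0")
        for d in (self.within_species_divergence,
                  self.between_species_divergence):
            if not 0.0 <= d < 1.0:
                raise ValueError("divergences must lie in [0, 1)")
        if self.within_species_divergence >= self.between_species_divergence:
            raise ValueError("within-species divergence must be < between")
        if self.target_species not in self.species_names():
            raise ValueError("target species not among species names")
        if (self.marker_homolog_identity is not None
                and self.marker_homolog_identity >= 0.5):
            warnings.warn(
                "marker_homolog_identity ≥ 0.5 will co-cluster with the "
                "marker at the conventional cutoff; exclusion tests will "
                "not behave as intended", stacklevel=2)


@dataclass
class GroundTruth:
    true_assignment: dict[GeneKey, str]       # gene → family id
    family_class: dict[str, str]              # family → core/accessory/unique/clade_specific
    marker_gene_ids: dict[str, list[str]]     # genome_id → planted marker gene ids
    marker_family_ids: list[str]
    species_of: dict[str, str]                # genome_id → species
    species_tree_newick: str


def expected_identity(divergence: float) -> float:
    """Expected ungapped identity of two sequences independently diverged
    from a common ancestor at per-lineage substitution rate ``divergence``.

    A site matches when neither lineage substituted, (1−d)², or both did
    and collided, d²/3 (substitutions are uniform over the 3 other bases).
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    d = divergence
    return (1.0 - d) ** 2 + d ** 2 / 3.0


# fraction of single random nucleotide substitutions that are synonymous
# under the standard code, used to invert amino-acid identity targets
_SYNONYMOUS_FRACTION = 0.24


def _aa_identity_model(q: float) -> float:
    """Approximate amino-acid identity after single-lineage nt rate q."""
    return (1.0 - q) ** 3 + 3.0 * q * (1.0 - q) ** 2 * _SYNONYMOUS_FRACTION


def nt_rate_for_aa_identity(aa_identity: float) -> float:
    """Single-lineage nucleotide substitution rate whose expected *aligned*
    amino-acid identity is ``aa_identity``.

    Bisection on the ungapped codon model, with a small Monte-Carlo-
    calibrated correction for the identity inflation a global aligner
    achieves by gapping (≈ +0.016 at 36% identity, vanishing near 100%).
    """
    if not 0.0 < aa_identity <= 1.0:
        raise ValueError("aa identity must lie in (0, 1]")
    target = aa_identity - 0.025 * (1.0 - aa_identity)
    lo, hi = 0.0, 0.95
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _aa_identity_model(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            indel_rate: float = 0.0) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        mask = rng.random(out.size) < rate
        n = int(mask.sum())
        if n:
            out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    if indel_rate > 0:
        keep = rng.random(out.size) >= indel_rate / 2
        out = out[keep]
        n_ins = int(rng.binomial(out.size, indel_rate / 2))
        if n_ins:
            pos = np.sort(rng.integers(0, out.size + 1, size=n_ins))
            out = np.insert(out, pos, rng.integers(0, 4, size=n_ins).astype(np.uint8))
    return out


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _codon_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo // 3, hi // 3 + 1)) * 3


def generate_community(spec: CommunitySpec) -> tuple[GenomeSet, GroundTruth]:
    """Emit a GenomeSet plus the ground truth it was built from.

    Deterministic per seed: same spec → byte-identical sequences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    species = spec.species_names()
    per_species = spec.resolved_genomes_per_species()
    lo, hi = spec.gene_length_range
    half_between = spec.between_species_divergence / 2.0
    half_within = spec.within_species_divergence / 2.0

    # ---- family ancestors ---------------------------------------------
    families: list[tuple[str, np.ndarray, set[str]]] = []  # id, seq, species
    all_species = set(species)
    for i in range(spec.n_core_genes):
        seq = _random_seq(rng, _codon_length(rng, lo, hi), spec.gc_target)
        families.append((f"core_{i + 1:04d}", seq, all_species))
    for i in range(spec.n_accessory_genes):
        seq = _random_seq(rng, _codon_length(rng, lo, hi), spec.gc_target)
        size = int(rng.integers(2, spec.n_species))  # 2 .. n_species-1
        subset = set(rng.choice(species, size=size, replace=False))
        families.append((f"acc_{i + 1:04d}", seq, subset))

    # planted markers: long enough to design a short amplicon inside
    marker_lo = max(lo, 360)
    markers: list[tuple[str, np.ndarray]] = []
    for i in range(spec.n_planted_markers):
        seq = _random_seq(rng, _codon_length(rng, marker_lo, max(hi, marker_lo)),
                          spec.gc_target)
        markers.append((f"marker_{i + 1:02d}", seq))

    homolog_species = None
    homologs: list[tuple[str, np.ndarray]] = []
    if spec.marker_homolog_identity is not None:
        nontarget = [s for s in species if s != spec.target_species]
        homolog_species = spec.marker_homolog_species or nontarget[0]
        if homolog_species == spec.target_species:
            raise ValueError("homolog host must be a non-target species")
        q = nt_rate_for_aa_identity(spec.marker_homolog_identity)
        for fam_id, seq in markers:
            homologs.append((f"{fam_id}_homolog", _mutate(rng, seq, q)))

    # ---- species-level sequences ---------------------------------------
    species_seqs: dict[tuple[str, str], np.ndarray] = {}
    for fam_id, anc, members in families:
        for sp in species:
            if sp in members:
                species_seqs[(fam_id, sp)] = _mutate(rng, anc, half_between,
                                                     spec.indel_rate)
    for fam_id, anc in markers:
        species_seqs[(fam_id, spec.target_species)] = anc.copy()
    for fam_id, anc in homologs:
        species_seqs[(fam_id, homolog_species)] = anc.copy()

    # ---- genomes --------------------------------------------------------
    genomes: list[GenomeRecord] = []
    truth_assign: dict[GeneKey, str] = {}
    marker_gene_ids: dict[str, list[str]] = {}
    species_of: dict[str, str] = {}
    family_order = ([f for f, _, _ in families]
                    + [f for f, _ in markers] + [f for f, _ in homologs])
    for sp in species:
        for g in range(per_species[sp]):
            genome_id = f"{sp}_g{g + 1}"
            species_of[genome_id] = sp
            genes: list[GeneRecord] = []
            markers_here: list[str] = []
            idx = 0
            for fam_id in family_order:
                key = (fam_id, sp)
                if key not in species_seqs:
                    continue
                idx += 1
                gene_id = f"g{idx:05d}"
                seq = _mutate(rng, species_seqs[key], half_within,
                              spec.indel_rate)
                genes.append(GeneRecord(gene_id=gene_id, seq=_decode(seq)))
                truth_assign[GeneKey(genome_id, gene_id)] = fam_id
                if fam_id in {m for m, _ in markers}:
                    markers_here.append(gene_id)
            genomes.append(GenomeRecord(genome_id=genome_id,
                                        species_label=sp, genes=genes))
            marker_gene_ids[genome_id] = markers_here

    # ---- family classes and species tree --------------------------------
    genome_count: dict[str, int] = {}
    for key, fam in truth_assign.items():
        genome_count[fam] = genome_count.get(fam, 0) + 1
    n_genomes = len(genomes)
    family_class = {}
    marker_ids = [m for m, _ in markers]
    for fam, cnt in genome_count.items():
        if fam in marker_ids:
            family_class[fam] = "clade_specific"
        elif cnt == n_genomes:
            family_class[fam] = "core"
        elif cnt == 1:
            family_class[fam] = "unique"
        else:
            family_class[fam] = "accessory"

    clades = []
    for sp in species:
        tips = ",".join(f"{sp}_g{g + 1}" for g in range(per_species[sp]))
        clades.append(f"({tips})" if per_species[sp] > 1 else tips)
    newick = "(" + ",".join(clades) + ");"

    genome_set = GenomeSet(genomes=genomes,
                           target_species=spec.target_species)
    truth = GroundTruth(true_assignment=truth_assign,
                        family_class=family_class,
                        marker_gene_ids=marker_gene_ids,
                        marker_family_ids=marker_ids,
                        species_of=species_of,
                        species_tree_newick=newick)
    return genome_set, truth


def scaled_spec(seed: int, **overrides) -> CommunitySpec:
    """A smaller community with the same cohort structure (9 species,
    5 target + 24 non-target genomes, planted marker + 36% homolog) used
    where many replicate communities are generated."""
    params = dict(n_core_genes=40, n_accessory_genes=30,
                  gene_length_range=(300, 600), seed=seed)
    params.update(overrides)
    return CommunitySpec(**params)


def truth_tables(truth: GroundTruth):
    """Ground truth as DataFrames (assignment, classes) for TSV export."""
    import pandas as pd
    assign = pd.DataFrame(
        [(k.genome_id, k.gene_id, fam)
         for k, fam in sorted(truth.true_assignment.items(),
                              key=lambda kv: (kv[0].genome_id, kv[0].gene_id))],
        columns=["genome_id", "gene_id", "family"])
    classes = pd.DataFrame(sorted(truth.family_class.items()),
                           columns=["family", "class"])
    return assign, classes
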