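#!/usr/bin/env python
"""Design a species-specific primer pair inside the selected marker
(windows restricted to positions conserved across all target-clade
copies) and validate it by in-silico PCR against every genome.

Reads marker.fasta + clusters.tsv + the community, writes primers.tsv and
specificity.tsv under results/analysis/.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from panmarker.genome_io import load_genome_set_dir
from panmarker.pipeline import load_clustering
from panmarker.primers import (conservation_mask, design_primers,
                               insilico_pcr, primer_table)

OUT = Path("results/analysis")


def main() -> None:
    gs = load_genome_set_dir(OUT / "community", target_species="species_01")
    rec = next(SeqIO.parse(str(OUT / "marker.fasta"), "fasta"))
    cluster_id, marker = rec.id, str(rec.seq)
    table = pd.read_csv(OUT / "clusters.tsv", sep="\t",
                        dtype={"genome_id": str, "gene_id": str})
    clustering = load_clustering(table, cutoff=0.50, space="protein")
    members = clustering.cluster(cluster_id).members
    mask = conservation_mask(
        marker, [gs.genome(m.genome_id).gene(m.gene_id).seq for m in members])

    pair = design_primers(marker, conserved_mask=mask)[0]
    primer_table([pair], species=gs.target_species).to_csv(
        OUT / "primers.tsv", sep="\t", index=False)
    report = insilico_pcr(pair, gs, tolerance=2)
    report.to_frame().to_csv(OUT / "specificity.tsv", sep="\t", index=False)

    print(f"forward  5'-{pair.forward_seq}-3'  (Tm {pair.forward_tm:.0f} C, "
          f"GC {100 * pair.forward_gc:.0f}%)")
    print(f"reverse  5'-{pair.reverse_seq}-3'  (Tm {pair.reverse_tm:.0f} C, "
          f"GC {100 * pair.reverse_gc:.0f}%)")
    print(f"product  {pair.product_size} bp")
    print(f"amplified {report.n_target_amplified}/"
          f"{len(report.target_genome_ids)} target genomes and "
          f"{report.n_nontarget_amplified}/{len(report.nontarget_genome_ids)} "
          f"non-target genomes -> specific={report.specific}")


if __name__ == "__main__":
    main()
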