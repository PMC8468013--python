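#!/usr/bin/env python
"""Cluster all genes into ortholog families (greedy centroid, 50% amino-
acid identity) and partition the pan-genome into core / accessory /
unique (singleton) classes.

Reads results/analysis/community/, writes clusters.tsv, pan_matrix.tsv
and partition.tsv next to it.
"""

from pathlib import Path

from panmarker.clustering import clustering_table, greedy_cluster
from panmarker.genome_io import load_genome_set_dir
from panmarker.pangenome import build_pan_matrix, partition

OUT = Path("results/analysis")


def main() -> None:
    gs = load_genome_set_dir(OUT / "community", target_species="species_01")
    clustering = greedy_cluster(gs, cutoff=0.50, space="protein")
    clustering_table(clustering, gs).to_csv(OUT / "clusters.tsv", sep="\t",
                                            index=False)
    pan = build_pan_matrix(clustering, gs)
    part = partition(pan)
    pan.to_frame().to_csv(OUT / "pan_matrix.tsv", sep="\t")
    part.to_frame().to_csv(OUT / "partition.tsv", sep="\t", index=False)
    print(f"{gs.n_genes} genes -> {len(clustering.clusters)} clusters")
    print(f"pan-genome {part.pan_size}: {len(part.core)} core, "
          f"{len(part.accessory)} accessory, {len(part.unique)} unique")


if __name__ == "__main__":
    main()
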