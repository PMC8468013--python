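#!/usr/bin/env python
"""Neighbor-joining trees of the cohort: one from Jaccard distances on
the gene presence/absence matrix, one from p-distances on 20 randomly
sampled single-copy core genes.  Checks that every species forms a clade.

Reads the community and clusters.tsv, writes pan_tree.nwk, core_tree.nwk
and monophyly.tsv under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from panmarker.genome_io import load_genome_set_dir, read_species_table
from panmarker.pangenome import build_pan_matrix
from panmarker.phylogeny import (core_concat_distance, neighbor_joining,
                                 pan_matrix_distance, species_monophyletic)
from panmarker.pipeline import load_clustering

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    gs = load_genome_set_dir(OUT / "community", target_species="species_01")
    table = pd.read_csv(OUT / "clusters.tsv", sep="\t",
                        dtype={"genome_id": str, "gene_id": str})
    clustering = load_clustering(table, cutoff=0.50, space="protein")
    pan = build_pan_matrix(clustering, gs)
    species_of = read_species_table(OUT / "community" / "species.tsv")

    pan_tree = neighbor_joining(pan_matrix_distance(pan, "jaccard"))
    (OUT / "pan_tree.nwk").write_text(pan_tree.to_newick() + "\n")
    core_tree = neighbor_joining(
        core_concat_distance(gs, clustering, n_clusters=20, seed=SEED))
    (OUT / "core_tree.nwk").write_text(core_tree.to_newick() + "\n")

    rows = []
    for name, tree in (("pan", pan_tree), ("core", core_tree)):
        mono = species_monophyletic(tree, species_of)
        for sp, ok in mono.items():
            rows.append({"tree": name, "species": sp, "monophyletic": ok})
        print(f"{name} tree: {sum(mono.values())}/{len(mono)} species "
              "monophyletic")
    pd.DataFrame(rows).to_csv(OUT / "monophyly.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
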