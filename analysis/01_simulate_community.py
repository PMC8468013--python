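#!/usr/bin/env python
"""Generate the study community: 9 species, 5 target + 24 non-target
genomes, 120 core + 80 accessory gene families, one planted clade-unique
marker gene and a ~36%-identity homolog of it in one non-target species.

Writes per-genome gene FASTAs, the species table and the ground truth to
results/analysis/community/.
"""

from pathlib import Path

from panmarker.genome_io import write_genome_set
from panmarker.simulate import CommunitySpec, generate_community, truth_tables

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    spec = CommunitySpec(seed=SEED)
    gs, truth = generate_community(spec)
    write_genome_set(gs, OUT / "community")
    assign, classes = truth_tables(truth)
    assign.to_csv(OUT / "truth_assignment.tsv", sep="\t", index=False)
    classes.to_csv(OUT / "truth_classes.tsv", sep="\t", index=False)
    (OUT / "species_tree.nwk").write_text(truth.species_tree_newick + "\n")
    n_marker = sum(bool(v) for v in truth.marker_gene_ids.values())
    print(f"community: {len(gs.genomes)} genomes, {gs.n_genes} genes "
          f"({len(gs.target_genomes)} genomes of {gs.target_species})")
    print(f"planted marker present in {n_marker} genomes; "
          f"ground truth written to {OUT}")


if __name__ == "__main__":
    main()
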