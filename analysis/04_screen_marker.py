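#!/usr/bin/env python
"""Clade-specificity screen: find the clusters present in every target-
species genome and absent everywhere else, quantify each survivor's
closest cross-species homolog, and rank by GC/length primer suitability.

Reads the community and clusters.tsv, writes screen_report.tsv and the
selected marker as marker.fasta under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from panmarker.clustering import representative_seq
from panmarker.genome_io import load_genome_set_dir
from panmarker.pangenome import build_pan_matrix
from panmarker.pipeline import load_clustering
from panmarker.screen import ScreenConfig, run_screen

OUT = Path("results/analysis")


def main() -> None:
    gs = load_genome_set_dir(OUT / "community", target_species="species_01")
    table = pd.read_csv(OUT / "clusters.tsv", sep="\t",
                        dtype={"genome_id": str, "gene_id": str})
    clustering = load_clustering(table, cutoff=0.50, space="protein")
    pan = build_pan_matrix(clustering, gs)
    cfg = ScreenConfig(target_species="species_01")
    report = run_screen(gs, clustering, pan, cfg)
    report.to_frame().to_csv(OUT / "screen_report.tsv", sep="\t", index=False)

    sel = report.selected
    marker = representative_seq(clustering, gs, sel.cluster_id)
    (OUT / "marker.fasta").write_text(f">{sel.cluster_id}\n{marker}\n")
    print(f"{len(report.shared_in_target)} cluster(s) exclusive to all "
          f"{len(gs.target_genomes)} target genomes; "
          f"{len(report.passed_homology)} passed the homology scan")
    cross = ("below the 30% report floor" if sel.below_floor
             else f"{100 * sel.max_cross_identity:.1f}% aa identity "
                  f"(best hit {sel.best_cross_hit[0]}:{sel.best_cross_hit[1]})")
    print(f"selected {sel.cluster_id}: {sel.length_nt} nt, "
          f"GC {100 * sel.gc:.1f}%, closest non-target homolog {cross}")


if __name__ == "__main__":
    main()
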