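"""Clade-specific marker gene screen.

Two stages mirror the discovery logic of comparative pan-genomics: first a
presence/absence screen keeps clusters found in *every* genome of the target
species and in *no* other genome, with high within-clade identity; second,
each survivor's representative is aligned against every non-target gene to
quantify its closest cross-species homolog — a candidate is discarded when
any homolog reaches the cross-identity ceiling.  Survivors are ranked for
primer-design suitability by GC content and gene length.

Within-clade identities are nucleotide-level (the scale on which strain
variants of one gene differ); cross-species homology is amino-acid-level,
the scale on which distant homologs are meaningfully compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .clustering import (ClusteringResult, GeneKey, pairwise_identity,
                         translate_cds)
from .genome_io import GenomeSet, compute_gc
from .pangenome import PanMatrix


@dataclass
class ScreenConfig:
    target_species: str
    within_identity_min: float = 0.94
    cross_identity_max: float = 0.50
    homology_report_floor: float = 0.30
    gc_ideal: tuple[float, float] = (0.40, 0.60)
    length_ideal: tuple[int, int] = (300, 2000)
    w_gc: float = 1.0
    w_len: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cross_identity_max <= self.within_identity_min <= 1.0:
            raise ValueError(
                "require 0 < cross_identity_max ≤ within_identity_min ≤ 1"
            )


@dataclass
class MarkerCandidate:
    cluster_id: str
    target_identities: dict[str, float]  # genome_id → nt identity to rep
    max_cross_identity: float
    best_cross_hit: Optional[tuple[str, str, float]]  # genome, gene, identity
    below_floor: bool
    gc: float
    length_nt: int
    rank_score: float = float("nan")


@dataclass
class ScreenReport:
    shared_in_target: list[str]
    passed_homology: list[MarkerCandidate]
    ranked: list[MarkerCandidate]

    @property
    def selected(self) -> MarkerCandidate:
        if not self.ranked:
            raise ValueError("no clade-specific marker found")
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.ranked:
            hit = c.best_cross_hit
            rows.append({
                "cluster_id": c.cluster_id,
                "n_target_genomes": len(c.target_identities),
                "within_identity_min": round(min(c.target_identities.values()), 4),
                "within_identity_max": round(max(c.target_identities.values()), 4),
                "max_cross_identity": ("<floor" if c.below_floor
                                       else round(c.max_cross_identity, 4)),
                "best_cross_hit": (f"{hit[0]}:{hit[1]}" if hit else ""),
                "gc": round(c.gc, 4),
                "length_nt": c.length_nt,
                "rank_score": round(c.rank_score, 6),
            })
        return pd.DataFrame(rows)


def _rep_gene(clustering: ClusteringResult, genome_set: GenomeSet,
              cluster_id: str):
    rep = clustering.cluster(cluster_id).representative
    return genome_set.genome(rep.genome_id).gene(rep.gene_id)


def shared_target_clusters(pan: PanMatrix, genome_set: GenomeSet,
                           clustering: ClusteringResult,
                           config: ScreenConfig) -> list[str]:
    """Clusters present in every target genome and absent from every other,
    whose target members all match the representative at ≥ within_identity_min
    (nucleotide identity)."""
    target_ids = [g.genome_id for g in genome_set.target_genomes]
    if not target_ids:
        raise ValueError(f"no genomes labelled {config.target_species!r}")
    target_set = set(target_ids)
    out = []
    for cl in clustering.clusters:
        genomes = cl.genome_ids
        if genomes != target_set:
            continue
        rep_seq = _rep_gene(clustering, genome_set, cl.cluster_id).seq
        ok = True
        for m in cl.members:
            seq = genome_set.genome(m.genome_id).gene(m.gene_id).seq
            if pairwise_identity(seq, rep_seq) < config.within_identity_min:
                ok = False
                break
        if ok:
            out.append(cl.cluster_id)
    return out


def cross_homology_scan(candidate_ids: list[str], genome_set: GenomeSet,
                        clustering: ClusteringResult,
                        config: ScreenConfig) -> list[MarkerCandidate]:
    """Align each candidate representative (amino acid) against every
    non-target gene; retain candidates whose best hit stays below the
    cross-identity ceiling.  Best hits below the report floor are flagged
    rather than attributed to a specific gene."""
    out = []
    for cid in candidate_ids:
        cl = clustering.cluster(cid)
        rep_gene = _rep_gene(clustering, genome_set, cid)
        rep_aa = translate_cds(rep_gene.seq)
        best = 0.0
        best_hit: Optional[tuple[str, str, float]] = None
        for genome in genome_set.nontarget_genomes:
            for gene in genome.genes:
                ident = pairwise_identity(rep_aa, translate_cds(gene.seq))
                if ident > best:
                    best = ident
                    best_hit = (genome.genome_id, gene.gene_id, ident)
        if best >= config.cross_identity_max:
            continue
        below = best < config.homology_report_floor
        rep_seq = rep_gene.seq
        target_idents = {
            m.genome_id: pairwise_identity(
                genome_set.genome(m.genome_id).gene(m.gene_id).seq, rep_seq)
            for m in cl.members
        }
        out.append(MarkerCandidate(
            cluster_id=cid,
            target_identities=target_idents,
            max_cross_identity=best,
            best_cross_hit=None if below else best_hit,
            below_floor=below,
            gc=compute_gc(rep_seq),
            length_nt=rep_gene.length_nt,
        ))
    return out


def _interval_distance(x: float, lo: float, hi: float) -> float:
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0.0


def rank_candidates(candidates: list[MarkerCandidate],
                    config: ScreenConfig) -> list[MarkerCandidate]:
    """Ascending rank_score = w_gc·gc_penalty + w_len·len_penalty.

    gc_penalty is the distance of the GC fraction from the ideal interval
    (0 inside); len_penalty is the distance of the length from the ideal
    interval normalized by the interval width.  Ties break on cluster_id.
    """
    if not candidates:
        raise ValueError("no clade-specific marker found")
    lo, hi = config.length_ideal
    width = max(hi - lo, 1)
    for c in candidates:
        gc_pen = _interval_distance(c.gc, *config.gc_ideal)
        len_pen = _interval_distance(c.length_nt, lo, hi) / width
        c.rank_score = config.w_gc * gc_pen + config.w_len * len_pen
    return sorted(candidates, key=lambda c: (c.rank_score, c.cluster_id))


def run_screen(genome_set: GenomeSet, clustering: ClusteringResult,
               pan: PanMatrix, config: ScreenConfig) -> ScreenReport:
    shared = shared_target_clusters(pan, genome_set, clustering, config)
    passed = cross_homology_scan(shared, genome_set, clustering, config)
    ranked = rank_candidates(passed, config) if passed else []
    return ScreenReport(shared_in_target=shared, passed_homology=passed,
                        ranked=ranked)
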