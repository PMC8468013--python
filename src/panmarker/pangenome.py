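"""Presence/absence pan-genome matrix and core/accessory/unique partition.

"Unique" means a cluster confined to exactly one *genome* (a singleton
cluster); a cluster confined to all genomes of one species is a
clade-specific marker and is handled by the screen, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusteringResult
from .genome_io import GenomeSet


@dataclass
class PanMatrix:
    """clusters × genomes copy-number matrix; presence is counts ≥ 1."""

    cluster_ids: list[str]
    genome_ids: list[str]
    counts: np.ndarray  # int, shape (n_clusters, n_genomes)

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int),
                            index=self.cluster_ids, columns=self.genome_ids)

    def row(self, cluster_id: str) -> np.ndarray:
        return self.presence[self.cluster_ids.index(cluster_id)]


@dataclass
class PanPartition:
    core: set[str]
    accessory: set[str]
    unique: set[str]

    @property
    def pan_size(self) -> int:
        return len(self.core) + len(self.accessory) + len(self.unique)

    def to_frame(self) -> pd.DataFrame:
        rows = [("core", len(self.core)), ("accessory", len(self.accessory)),
                ("unique", len(self.unique)), ("pan", self.pan_size)]
        return pd.DataFrame(rows, columns=["class", "n_clusters"])


def build_pan_matrix(clustering: ClusteringResult,
                     genome_set: GenomeSet) -> PanMatrix:
    """Count cluster members per genome (paralogs counted as copies)."""
    if not clustering.clusters:
        raise ValueError("build_pan_matrix: empty cluster list")
    genome_ids = genome_set.genome_ids
    gpos = {g: j for j, g in enumerate(genome_ids)}
    cluster_ids = [c.cluster_id for c in clustering.clusters]
    counts = np.zeros((len(cluster_ids), len(genome_ids)), dtype=int)
    for i, cl in enumerate(clustering.clusters):
        for m in cl.members:
            if m.genome_id not in gpos:
                raise ValueError(
                    f"cluster {cl.cluster_id}: member genome "
                    f"{m.genome_id!r} not in genome set"
                )
            counts[i, gpos[m.genome_id]] += 1
    total = sum(g.n_genes for g in genome_set.genomes)
    assigned = int(counts.sum())
    if assigned != total:
        raise ValueError(
            f"clustering covers {assigned} genes but genome set has {total}"
        )
    return PanMatrix(cluster_ids=cluster_ids, genome_ids=genome_ids,
                     counts=counts)


def partition(pan: PanMatrix) -> PanPartition:
    """Split clusters into core / accessory / unique (singleton) classes.

    With a single genome every cluster is simultaneously "present in all
    genomes" and "present in exactly one"; such clusters are classed core.
    """
    n_genomes = len(pan.genome_ids)
    if n_genomes < 1:
        raise ValueError("partition: no genomes")
    npresent = pan.presence.sum(axis=1)
    core, accessory, unique = set(), set(), set()
    for cid, n in zip(pan.cluster_ids, npresent):
        if n == n_genomes:
            core.add(cid)
        elif n == 1:
            unique.add(cid)
        else:
            accessory.add(cid)
    return PanPartition(core=core, accessory=accessory, unique=unique)
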