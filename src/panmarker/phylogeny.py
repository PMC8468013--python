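"""Distance-based phylogenies over the genome cohort.

Two distance substrates are provided — gene-content (Jaccard or Hamming on
the presence/absence pan-matrix) and sequence divergence (p-distance on a
concatenation of randomly sampled single-copy core clusters) — both fed to
classical neighbor-joining (Saitou–Nei).  NJ is written here so that
tie-breaking is deterministic (lexicographic on node labels) and negative
branch-length estimates are clamped to zero and flagged; scikit-bio's NJ
serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .clustering import ClusteringResult, project_onto_rep
from .genome_io import GenomeSet
from .pangenome import PanMatrix


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class PhyloTree:
    """A tree over genome labels, serializable as Newick."""

    root: TreeNode
    negative_branches_clamped: int = 0

    def to_newick(self) -> str:
        return str(self.root).strip()

    @property
    def tip_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the canonical smaller side."""
        tips = self.tip_names
        out = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(tips) - 1:
                other = frozenset(tips - side)
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def pan_matrix_distance(pan: PanMatrix, metric: str = "jaccard") -> DistanceMatrix:
    """Gene-content distance between genomes from the presence matrix."""
    pres = pan.presence  # clusters × genomes
    n = pres.shape[1]
    d = np.zeros((n, n))
    if metric == "jaccard":
        if (pres.sum(axis=0) == 0).any():
            empty = [g for g, s in zip(pan.genome_ids, pres.sum(axis=0)) if s == 0]
            raise ValueError(f"jaccard undefined for empty genomes {empty}")
        for i in range(n):
            for j in range(i + 1, n):
                inter = np.logical_and(pres[:, i], pres[:, j]).sum()
                union = np.logical_or(pres[:, i], pres[:, j]).sum()
                d[i, j] = d[j, i] = 1.0 - inter / union
    elif metric == "hamming":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(pres[:, i] != pres[:, j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=list(pan.genome_ids), d=d)


def single_copy_core_clusters(clustering: ClusteringResult,
                              genome_set: GenomeSet) -> list[str]:
    """Clusters with exactly one member in every genome."""
    n = len(genome_set.genomes)
    out = []
    for cl in clustering.clusters:
        counts: dict[str, int] = {}
        for m in cl.members:
            counts[m.genome_id] = counts.get(m.genome_id, 0) + 1
        if len(counts) == n and all(v == 1 for v in counts.values()):
            out.append(cl.cluster_id)
    return out


def core_concat_distance(genome_set: GenomeSet, clustering: ClusteringResult,
                         n_clusters: int = 20, seed: int = 0) -> DistanceMatrix:
    """p-distance on a seeded sample of concatenated single-copy core genes.

    Each cluster's members are projected onto the cluster representative
    (pairwise, gap-excluded) and the per-genome rows are concatenated across
    the sampled clusters; the distance between two genomes is mismatched
    columns / compared columns over positions where neither is gapped.
    """
    sc = single_copy_core_clusters(clustering, genome_set)
    if len(sc) < n_clusters:
        raise ValueError(
            f"need {n_clusters} single-copy core clusters, found {len(sc)}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(sorted(sc), size=n_clusters, replace=False))
    genome_ids = genome_set.genome_ids
    rows: dict[str, list[str]] = {g: [] for g in genome_ids}
    for cid in chosen:
        cl = clustering.cluster(cid)
        rep_gene = genome_set.genome(cl.representative.genome_id).gene(
            cl.representative.gene_id)
        rep = rep_gene.seq
        for m in cl.members:
            member = genome_set.genome(m.genome_id).gene(m.gene_id).seq
            rows[m.genome_id].append(project_onto_rep(rep, member))
    mat = np.array([list("".join(rows[g])) for g in genome_ids])
    n = len(genome_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != "-") & (mat[j] != "-")
            if not ok.any():
                raise ValueError(
                    f"no comparable columns between {genome_ids[i]} "
                    f"and {genome_ids[j]}"
                )
            d[i, j] = d[j, i] = np.mean(mat[i][ok] != mat[j][ok])
    return DistanceMatrix(labels=list(genome_ids), d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ; deterministic lexicographic tie-breaking on Q.

    Exact on additive matrices.  Negative branch-length estimates are
    clamped to zero and counted in ``negative_branches_clamped``.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor_joining needs ≥3 labels")
    # active nodes: (sort_key, TreeNode); key = lexicographically smallest tip
    nodes: list[tuple[str, TreeNode]] = [
        (lab, TreeNode(name=lab)) for lab in dm.labels
    ]
    d = dm.d.copy()
    clamped = 0

    def join(i: int, j: int, li: float, lj: float) -> None:
        nonlocal clamped, d, nodes
        ki, ni = nodes[i]
        kj, nj = nodes[j]
        for length, child in ((li, ni), (lj, nj)):
            if length < 0:
                clamped += 1
            child.length = max(0.0, float(length))
        parent = TreeNode(children=[ni, nj])
        new_key = min(ki, kj)
        m = d.shape[0]
        keep = [x for x in range(m) if x not in (i, j)]
        du = 0.5 * (d[i, keep] + d[j, keep] - d[i, j])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        nodes = [nodes[x] for x in keep] + [(new_key, parent)]

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = [(i, j) for i in range(m) for j in range(i + 1, m)
                if q[i, j] <= qmin + 1e-12]
        i, j = min(ties, key=lambda p: (min(nodes[p[0]][0], nodes[p[1]][0]),
                                        max(nodes[p[0]][0], nodes[p[1]][0])))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        join(i, j, li, lj)

    (ka, a), (kb, b) = nodes
    half = d[0, 1] / 2.0
    if half < 0:
        clamped += 1
        half = 0.0
    a.length = b.length = half
    root = TreeNode(children=[a, b] if ka <= kb else [b, a])
    return PhyloTree(root=root, negative_branches_clamped=clamped)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if t1.tip_names != t2.tip_names:
        raise ValueError("trees must share the same tip set")
    return len(t1.splits() ^ t2.splits())


def species_monophyletic(tree: PhyloTree,
                         species_of: dict[str, str]) -> dict[str, bool]:
    """Per species: do its genomes form a clade (in the unrooted sense)?"""
    tips = tree.tip_names
    splits = tree.splits()
    out = {}
    for sp in sorted(set(species_of.values())):
        members = frozenset(g for g, s in species_of.items() if s == sp)
        if len(members) <= 1 or len(members) >= len(tips) - 1:
            out[sp] = True
            continue
        canon = min(members, frozenset(tips - members),
                    key=lambda s: (len(s), sorted(s)))
        out[sp] = canon in splits
    return out


def parse_newick(newick: str) -> PhyloTree:
    import io
    root = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    return PhyloTree(root=root)


def tree_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix implied by the tree."""
    skdm = tree.root.tip_tip_distances()
    labels = sorted(skdm.ids)
    d = np.array([[skdm[a, b] for b in labels] for a in labels])
    return DistanceMatrix(labels=labels, d=d)
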