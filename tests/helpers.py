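"""Test utilities and independent oracles.

The oracles here are deliberately separate from the package code paths they
check: a plain dynamic-programming global aligner for identity values, and
a from-scratch additive-tree builder for neighbor-joining exactness.
"""

from __future__ import annotations

import random

import numpy as np

from panmarker.genome_io import GeneRecord, GenomeRecord


def make_genome(genome_id: str, species: str,
                genes: list[tuple[str, str]]) -> GenomeRecord:
    return GenomeRecord(genome_id=genome_id, species_label=species,
                        genes=[GeneRecord(gene_id=g, seq=s) for g, s in genes])


def random_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT")
        for _ in range(n)
    )


def mutate_dna(rng: random.Random, seq: str, rate: float) -> str:
    return "".join(
        rng.choice([b for b in "ACGT" if b != c]) if rng.random() < rate else c
        for c in seq
    )


def nw_identity_oracle(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap_open: int = -2, gap_extend: int = -1) -> float:
    """Brute-force affine-gap global alignment; identity = matches/columns.

    Three-state Gotoh DP with full traceback, O(nm). Among co-optimal
    alignments the traceback prefers diagonal moves, which maximizes
    matches at equal score.
    """
    n, m = len(a), len(b)
    NEG = -10 ** 9
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # a[i-1]~b[j-1]
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in b
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in a
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback counting matches and columns
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    matches = cols = 0
    while i > 0 or j > 0:
        if state == 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            matches += a[i - 1] == b[j - 1]
            cols += 1
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax([p == M[i, j] - s for p in prev]))
            target = M[i, j] - s
            state = next(k for k, p in enumerate(prev) if p == target)
            i, j = i - 1, j - 1
        elif state == 1:
            cols += 1
            if X[i, j] == M[i - 1, j] + gap_open:
                state = 0
            i -= 1
        else:
            cols += 1
            if Y[i, j] == M[i, j - 1] + gap_open:
                state = 0
            j -= 1
    return matches / cols


def random_additive_tree(rng: random.Random, n_taxa: int):
    """Random binary tree and its exact path-length distance matrix.

    Built by sequential taxon attachment on explicit edges; distances are
    accumulated by graph traversal, independent of any tree library.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); internal nodes get ids ≥ n
    adj: dict[object, list] = {labels[0]: [], labels[1]: []}
    L = round(rng.uniform(0.2, 2.0), 3)
    adj[labels[0]].append((labels[1], L))
    adj[labels[1]].append((labels[0], L))
    next_internal = 0
    edges = [(labels[0], labels[1])]
    for lab in labels[2:]:
        u, v = edges[rng.randrange(len(edges))]
        # split edge (u,v) at new internal node w, attach lab
        w = f"I{next_internal}"
        next_internal += 1
        length = next(l for x, l in adj[u] if x == v)
        l1 = round(length * rng.uniform(0.2, 0.8), 4)
        l2 = round(length - l1, 4)
        l3 = round(rng.uniform(0.2, 2.0), 3)
        adj[u] = [(x, l) for x, l in adj[u] if x != v] + [(w, l1)]
        adj[v] = [(x, l) for x, l in adj[v] if x != u] + [(w, l2)]
        adj[w] = [(u, l1), (v, l2), (lab, l3)]
        adj[lab] = [(w, l3)]
        edges.remove((u, v))
        edges += [(u, w), (w, v), (w, lab)]
    # all-pairs leaf distances by BFS from each leaf
    d = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, l in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + l
                    stack.append(y)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    d = (d + d.T) / 2.0  # kill float asymmetry from traversal order
    return labels, d
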