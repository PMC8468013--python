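"""Distances, neighbor-joining exactness, Newick I/O, species monophyly."""

import io
import random

import numpy as np
import pytest

from panmarker.clustering import greedy_cluster
from panmarker.genome_io import GenomeSet
from panmarker.pangenome import PanMatrix, build_pan_matrix
from panmarker.phylogeny import (DistanceMatrix, core_concat_distance,
                                 neighbor_joining, pan_matrix_distance,
                                 parse_newick, robinson_foulds,
                                 species_monophyletic, tree_distances)
from panmarker.simulate import CommunitySpec, generate_community

from helpers import make_genome, mutate_dna, random_additive_tree, random_dna


def _pan(presence: np.ndarray, genomes=None) -> PanMatrix:
    n_c, n_g = presence.shape
    return PanMatrix(cluster_ids=[f"c{i}" for i in range(n_c)],
                     genome_ids=genomes or [f"G{i}" for i in range(n_g)],
                     counts=presence.astype(int))


class TestPanMatrixDistance:
    def test_identical_vectors_zero(self):
        pres = np.array([[1, 1], [0, 0], [1, 1]])
        for metric in ("jaccard", "hamming"):
            dm = pan_matrix_distance(_pan(pres), metric)
            assert dm.d[0, 1] == 0.0

    def test_jaccard_direct_count(self):
        pres = np.array([[1, 0], [1, 1], [0, 1]])
        dm = pan_matrix_distance(_pan(pres), "jaccard")
        assert dm.d[0, 1] == pytest.approx(1 - 1 / 3)

    def test_hamming_direct_count(self):
        pres = np.array([[1, 0], [1, 1], [0, 1]])
        dm = pan_matrix_distance(_pan(pres), "hamming")
        assert dm.d[0, 1] == pytest.approx(2 / 3)

    def test_matches_set_arithmetic_oracle(self, rng):
        pres = np.array([[rng.random() < 0.6 for _ in range(6)]
                         for _ in range(40)])
        dm = pan_matrix_distance(_pan(pres), "jaccard")
        for i in range(6):
            a = {k for k in range(40) if pres[k, i]}
            for j in range(6):
                b = {k for k in range(40) if pres[k, j]}
                want = 0.0 if i == j else 1 - len(a & b) / len(a | b)
                assert dm.d[i, j] == pytest.approx(want)

    def test_empty_genome_rejected_under_jaccard(self):
        pres = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="empty"):
            pan_matrix_distance(_pan(pres), "jaccard")

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="metric"):
            pan_matrix_distance(_pan(np.array([[1, 1]])), "cosine")


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) → path distances below
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        got = tree_distances(tree)
        assert got.labels == labels
        np.testing.assert_allclose(got.d, d, atol=1e-9)
        assert tree.splits() == {frozenset({"A", "B"})}

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        got = tree_distances(tree)
        np.testing.assert_allclose(got.d, d, atol=1e-9)

    def test_exact_on_random_additive_matrices(self):
        """NJ recovers random additive trees (≤8 taxa) exactly: implied
        path distances reproduce the input matrix."""
        rng = random.Random(7)
        for _ in range(15):
            labels, d = random_additive_tree(rng, rng.randint(4, 8))
            tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
            got = tree_distances(tree)
            order = [got.labels.index(l) for l in labels]
            np.testing.assert_allclose(got.d[np.ix_(order, order)], d,
                                       atol=1e-8)

    def test_agrees_with_skbio_topology(self):
        """Independent oracle: scikit-bio's NJ yields the same topology."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = random.Random(11)
        for _ in range(5):
            labels, d = random_additive_tree(rng, 6)
            ours = neighbor_joining(DistanceMatrix(labels=labels, d=d))
            theirs = sk_nj(SkDM(d, ids=labels))
            from panmarker.phylogeny import PhyloTree
            assert robinson_foulds(ours, PhyloTree(root=theirs)) == 0

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        labels = ["B", "D", "A", "C"]
        t1 = neighbor_joining(DistanceMatrix(labels=labels, d=d.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels=labels, d=d.copy()))
        assert t1.to_newick() == t2.to_newick()

    def test_rejects_asymmetric_and_small(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="≥3"):
            neighbor_joining(DistanceMatrix(labels=["A", "B"],
                                            d=np.zeros((2, 2))))

    def test_negative_estimates_clamped(self):
        # strongly non-additive matrix provokes negative branch estimates
        d = np.array([
            [0.0, 1.0, 0.1, 1.0],
            [1.0, 0.0, 1.0, 0.1],
            [0.1, 1.0, 0.0, 1.0],
            [1.0, 0.1, 1.0, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(labels=list("ABCD"), d=d))
        for node in tree.root.traverse(include_self=False):
            assert node.length >= 0.0

    def test_newick_round_trip(self):
        rng = random.Random(3)
        labels, d = random_additive_tree(rng, 7)
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        back = parse_newick(tree.to_newick())
        assert back.splits() == tree.splits()
        np.testing.assert_allclose(tree_distances(back).d,
                                   tree_distances(tree).d, atol=1e-9)


class TestCoreConcatDistance:
    def _two_clade_set(self, rng, divergence):
        n_genes = 6
        ancestors = [random_dna(rng, 300) for _ in range(n_genes)]
        genomes = []
        for sp, mult in (("X", 0), ("Y", 1)):
            sp_seqs = [mutate_dna(rng, a, divergence / 2 * mult * 2)
                       for a in ancestors]
            # two identical genomes per clade (zero within divergence)
            for g in range(2):
                genes = [(f"f{j}", sp_seqs[j]) for j in range(n_genes)]
                genomes.append(make_genome(f"{sp}{g}", sp, genes))
        return GenomeSet(genomes=genomes, target_species="X")

    def test_identical_genomes_zero(self, rng):
        gs = self._two_clade_set(rng, 0.0)
        clustering = greedy_cluster(gs, space="nucleotide", cutoff=0.8)
        dm = core_concat_distance(gs, clustering, n_clusters=4, seed=1)
        np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)

    def test_between_clade_divergence_recovered(self, rng):
        gs = self._two_clade_set(rng, 0.10)
        clustering = greedy_cluster(gs, space="nucleotide", cutoff=0.8)
        dm = core_concat_distance(gs, clustering, n_clusters=5, seed=1)
        i, j = dm.labels.index("X0"), dm.labels.index("Y0")
        assert dm.d[i, j] == pytest.approx(0.10, abs=0.02)
        assert dm.d[dm.labels.index("X0"), dm.labels.index("X1")] == 0.0

    def test_seed_determinism(self, community):
        gs, _ = community
        clustering = greedy_cluster(gs)
        d1 = core_concat_distance(gs, clustering, n_clusters=10, seed=5)
        d2 = core_concat_distance(gs, clustering, n_clusters=10, seed=5)
        np.testing.assert_array_equal(d1.d, d2.d)

    def test_shortfall_error_names_counts(self, rng):
        gs = self._two_clade_set(rng, 0.05)
        clustering = greedy_cluster(gs, space="nucleotide", cutoff=0.8)
        with pytest.raises(ValueError, match="found 6"):
            core_concat_distance(gs, clustering, n_clusters=50, seed=1)


class TestSpeciesMonophyly:
    def test_pan_and_core_trees_cluster_by_species(self, community):
        """Low within- vs between-species divergence ⇒ every species forms
        a clade on both trees, and every planted species-tree bipartition
        is present (zero RF mismatch against the multifurcating truth)."""
        gs, truth = community
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        pan_tree = neighbor_joining(pan_matrix_distance(pan, "jaccard"))
        core_tree = neighbor_joining(
            core_concat_distance(gs, clustering, n_clusters=10, seed=0))
        planted = parse_newick(truth.species_tree_newick)
        for tree in (pan_tree, core_tree):
            mono = species_monophyletic(tree, truth.species_of)
            assert all(mono.values()), mono
            assert planted.splits() <= tree.splits()
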