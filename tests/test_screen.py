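"""Clade-specificity screen: presence/absence stage, cross-homology scan,
candidate ranking, and the soundness of the end-to-end selection."""

import pytest

from panmarker.clustering import GeneKey, greedy_cluster, pairwise_identity, translate_cds
from panmarker.genome_io import GenomeSet
from panmarker.pangenome import build_pan_matrix
from panmarker.screen import (MarkerCandidate, ScreenConfig,
                              cross_homology_scan, rank_candidates,
                              run_screen, shared_target_clusters)
from panmarker.simulate import generate_community, scaled_spec

from helpers import make_genome, mutate_dna, random_dna


def _cand(cid, gc, length):
    return MarkerCandidate(cluster_id=cid, target_identities={"G1": 1.0},
                           max_cross_identity=0.2, best_cross_hit=None,
                           below_floor=True, gc=gc, length_nt=length)


class TestRankCandidates:
    CFG = ScreenConfig(target_species="X")

    def test_ideal_gc_beats_high_gc(self):
        a, b = _cand("A", 0.48, 900), _cand("B", 0.70, 900)
        assert [c.cluster_id for c in rank_candidates([b, a], self.CFG)] == ["A", "B"]

    def test_too_short_penalized(self):
        a, c = _cand("A", 0.48, 900), _cand("C", 0.48, 120)
        assert rank_candidates([c, a], self.CFG)[0].cluster_id == "A"

    def test_full_order_matches_recomputed_scores(self):
        cands = [_cand("A", 0.48, 900), _cand("B", 0.70, 900),
                 _cand("C", 0.48, 120), _cand("D", 0.35, 2500),
                 _cand("E", 0.55, 400)]
        ranked = rank_candidates(list(cands), self.CFG)

        def score(c):  # independent recomputation of the two penalties
            gc_pen = max(0.40 - c.gc, 0.0) + max(c.gc - 0.60, 0.0)
            len_pen = (max(300 - c.length_nt, 0) + max(c.length_nt - 2000, 0)) / 1700
            return gc_pen + len_pen
        want = sorted(cands, key=lambda c: (score(c), c.cluster_id))
        assert [c.cluster_id for c in ranked] == [c.cluster_id for c in want]
        for c in ranked:
            assert c.rank_score == pytest.approx(score(c))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no clade-specific marker"):
            rank_candidates([], self.CFG)


def _screen_fixture(rng):
    """5 target + 4 non-target genomes; planted marker in all targets,
    a core gene everywhere, a gene in only 4/5 targets, and a gene shared
    by targets plus one non-target."""
    marker = random_dna(rng, 450)
    core = random_dna(rng, 450)
    partial = random_dna(rng, 450)
    leaky = random_dna(rng, 450)
    genomes = []
    for i in range(5):
        genes = [("core", mutate_dna(rng, core, 0.01)),
                 ("marker", mutate_dna(rng, marker, 0.01)),
                 ("leaky", mutate_dna(rng, leaky, 0.01))]
        if i < 4:
            genes.append(("partial", mutate_dna(rng, partial, 0.01)))
        genomes.append(make_genome(f"T{i}", "X", genes))
    for i in range(4):
        genes = [("core", mutate_dna(rng, core, 0.06))]
        if i == 0:
            genes.append(("leaky", mutate_dna(rng, leaky, 0.06)))
        genomes.append(make_genome(f"N{i}", f"Y{i // 2}", genes))
    return GenomeSet(genomes=genomes, target_species="X"), marker


class TestSharedTargetClusters:
    def test_presence_absence_logic(self, rng):
        gs, marker = _screen_fixture(rng)
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        cfg = ScreenConfig(target_species="X")
        shared = shared_target_clusters(pan, gs, clustering, cfg)
        # exactly two clusters live in all 5 targets and nowhere else:
        # the marker and the 'partial' gene is only in 4 → excluded;
        # 'leaky' is also in N0 → excluded; 'core' is everywhere → excluded.
        seqs = set()
        for cid in shared:
            rep = clustering.cluster(cid).representative
            seqs.add(gs.genome(rep.genome_id).gene(rep.gene_id).gene_id)
        assert seqs == {"marker"}

    def test_low_within_identity_excluded(self, rng):
        gs, _ = _screen_fixture(rng)
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        strict = ScreenConfig(target_species="X", within_identity_min=0.999)
        assert shared_target_clusters(pan, gs, clustering, strict) == []

    def test_no_target_genomes_error(self, rng):
        gs, _ = _screen_fixture(rng)
        cfg = ScreenConfig(target_species="Z")
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        object.__setattr__  # noqa: B018 - GenomeSet validated target at build
        with pytest.raises(ValueError, match="no genomes labelled"):
            gs2 = GenomeSet(genomes=gs.genomes, target_species="X")
            gs2.target_species = "Z"
            shared_target_clusters(pan, gs2, clustering, cfg)


class TestCrossHomologyScan:
    def test_distant_homolog_reported_not_excluded(self, community):
        """The planted ~36% homolog is surfaced with its identity but the
        marker candidate is retained (ceiling is 50%)."""
        gs, truth = community
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        report = run_screen(gs, clustering, pan,
                            ScreenConfig(target_species="species_01"))
        sel = report.selected
        assert not sel.below_floor
        assert 0.25 <= sel.max_cross_identity < 0.50
        genome_id, gene_id, ident = sel.best_cross_hit
        assert truth.true_assignment[GeneKey(genome_id, gene_id)].endswith(
            "_homolog")

    def test_close_homolog_defeats_screen(self):
        """A homolog above the clustering cutoff joins the marker cluster,
        so the cluster is no longer target-exclusive and nothing passes."""
        spec = scaled_spec(seed=3, marker_homolog_identity=0.75)
        with pytest.warns(UserWarning, match="co-cluster"):
            gs, _ = generate_community(spec)
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        report = run_screen(gs, clustering, pan,
                            ScreenConfig(target_species="species_01"))
        assert report.passed_homology == []

    def test_no_homolog_reported_below_floor(self):
        gs, _ = generate_community(scaled_spec(
            seed=4, marker_homolog_identity=None))
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        report = run_screen(gs, clustering, pan,
                            ScreenConfig(target_species="species_01"))
        sel = report.selected
        assert sel.below_floor
        assert sel.best_cross_hit is None

    def test_tightening_ceiling_never_adds_candidates(self, community):
        gs, _ = community
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        prev = None
        for ceiling in (0.50, 0.40, 0.32):
            cfg = ScreenConfig(target_species="species_01",
                               cross_identity_max=ceiling,
                               homology_report_floor=0.2)
            shared = shared_target_clusters(pan, gs, clustering, cfg)
            passed = {c.cluster_id
                      for c in cross_homology_scan(shared, gs, clustering, cfg)}
            if prev is not None:
                assert passed <= prev
            prev = passed


class TestScreenSoundness:
    def test_selected_marker_satisfies_predicates_independently(self, community):
        """Re-check the selected candidate straight against the genome set,
        without the clustering bookkeeping: a high-identity copy in every
        target genome, no amino-acid homolog ≥ the ceiling anywhere else."""
        gs, _ = community
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        cfg = ScreenConfig(target_species="species_01")
        report = run_screen(gs, clustering, pan, cfg)
        sel = report.selected
        rep_key = clustering.cluster(sel.cluster_id).representative
        rep_nt = gs.genome(rep_key.genome_id).gene(rep_key.gene_id).seq
        rep_aa = translate_cds(rep_nt)
        for genome in gs.target_genomes:
            best = max(pairwise_identity(g.seq, rep_nt)
                       for g in genome.genes
                       if abs(g.length_nt - len(rep_nt)) < 100)
            assert best >= cfg.within_identity_min
        for genome in gs.nontarget_genomes:
            for gene in genome.genes:
                assert pairwise_identity(rep_aa, translate_cds(gene.seq)) \
                    < cfg.cross_identity_max

    def test_report_nesting_invariant(self, community):
        gs, _ = community
        clustering = greedy_cluster(gs)
        pan = build_pan_matrix(clustering, gs)
        report = run_screen(gs, clustering, pan,
                            ScreenConfig(target_species="species_01"))
        passed_ids = {c.cluster_id for c in report.passed_homology}
        assert passed_ids <= set(report.shared_in_target)
        assert report.selected.cluster_id in passed_ids
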