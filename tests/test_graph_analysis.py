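"""Evaluation, similarity, subtype detection, centralities, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bca.graph_analysis import (
    MicrocircuitSubtyper,
    compare_subtypes,
    detect_subtypes,
    dice_similarity,
    evaluate_structure,
    graph_centrality,
    representative_graph,
    similarity_matrix,
)
from bca.graphical_models import Microcircuit

NODES4 = ("n1", "n2", "n3", "n4")


def _g(edges, nodes=NODES4):
    return Microcircuit.from_edges(nodes, edges)


class TestEvaluateStructure:
    def test_perfect_recovery(self, six_node):
        _, gt = six_node
        ev = evaluate_structure(gt, gt)
        assert (ev.n_edges_gt, ev.n_empty_gt) == (6, 9)
        assert ev.tpr == 1.0 and ev.fpr == 0.0

    def test_edgeless_estimate(self, six_node):
        _, gt = six_node
        ev = evaluate_structure(Microcircuit(gt.node_labels), gt)
        assert ev.tpr == 0.0 and ev.fpr == 0.0

    def test_hand_counted_example(self):
        gt = _g([("n1", "n2"), ("n2", "n3")])
        est = _g([("n1", "n2"), ("n3", "n4")])
        ev = evaluate_structure(est, gt)
        assert (ev.tp, ev.fp) == (1, 1)
        assert ev.tpr == 0.5 and ev.fpr == 0.25

    def test_accounting_identities(self):
        gt = _g([("n1", "n2"), ("n2", "n3")])
        est = _g([("n1", "n2"), ("n3", "n4"), ("n1", "n4")])
        ev = evaluate_structure(est, gt)
        assert ev.tp + ev.fn == ev.n_edges_gt
        assert ev.fp + ev.tn == ev.n_empty_gt
        assert ev.sensitivity == ev.tpr
        assert ev.specificity == 1.0 - ev.fpr

    def test_subset_restriction(self):
        gt = Microcircuit.from_edges(("a", "b", "c"), [("a", "b")])
        est = Microcircuit.from_edges(("a", "b", "d"), [("a", "b")])
        ev = evaluate_structure(est, gt, nodes=("a", "b"))
        assert ev.tp == 1 and ev.fp == 0

    def test_node_mismatch_without_subset_raises(self):
        with pytest.raises(ValueError, match="node"):
            evaluate_structure(Microcircuit(("a", "b")), Microcircuit(("a", "c")))


class TestDiceSimilarity:
    def test_identical_graphs_score_one(self):
        g = _g([("n1", "n2"), ("n2", "n3")])
        assert dice_similarity(g, g) == 1.0

    def test_disjoint_edge_sets_score_zero(self):
        assert dice_similarity(_g([("n1", "n2")]), _g([("n3", "n4")])) == 0.0

    def test_hand_computed_overlap(self):
        nodes = ("a", "b", "c", "d", "e")
        g1 = _g([("a", "b"), ("b", "c"), ("c", "d")], nodes)
        g2 = _g([("a", "b"), ("b", "c"), ("c", "e")], nodes)
        assert dice_similarity(g1, g2) == pytest.approx(2 * 2 / 6)

    def test_two_empty_graphs_score_one(self):
        assert dice_similarity(Microcircuit(NODES4), Microcircuit(NODES4)) == 1.0

    @settings(max_examples=40, derandomize=True)
    @given(st.sets(st.tuples(st.integers(0, 4), st.integers(0, 4))),
           st.sets(st.tuples(st.integers(0, 4), st.integers(0, 4))))
    def test_bounds_symmetry_identity(self, e1, e2):
        nodes = tuple(f"v{i}" for i in range(5))
        mk = lambda es: Microcircuit.from_edges(
            nodes, {(f"v{min(a,b)}", f"v{max(a,b)}") for a, b in es if a != b})
        g1, g2 = mk(e1), mk(e2)
        d12 = dice_similarity(g1, g2)
        assert 0.0 <= d12 <= 1.0
        assert d12 == dice_similarity(g2, g1)
        if g1.n_edges or g2.n_edges:
            assert (d12 == 1.0) == (g1.edges() == g2.edges())


class TestSimilarityMatrix:
    def test_identical_list_gives_all_ones(self):
        g = _g([("n1", "n2")])
        np.testing.assert_array_equal(similarity_matrix([g, g, g]), np.ones((3, 3)))

    def test_symmetric_unit_diagonal(self):
        graphs = [_g([("n1", "n2")]), _g([("n2", "n3")]),
                  _g([("n1", "n2"), ("n2", "n3")])]
        sim = similarity_matrix(graphs)
        assert np.array_equal(sim, sim.T)
        np.testing.assert_array_equal(np.diag(sim), 1.0)
        assert sim[0, 2] == pytest.approx(2 * 1 / 3)


class TestDetectSubtypes:
    def _planted(self, n_per=6, within=0.9, between=0.05):
        m = 2 * n_per
        sim = np.full((m, m), between)
        sim[:n_per, :n_per] = within
        sim[n_per:, n_per:] = within
        np.fill_diagonal(sim, 1.0)
        return sim

    def test_planted_partition_recovered(self):
        labels = detect_subtypes(self._planted(), seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_single_graph_single_cluster(self):
        assert detect_subtypes(np.ones((1, 1)), seed=0).tolist() == [0]

    def test_reordering_invariance_up_to_relabeling(self):
        sim = self._planted()
        rng = np.random.default_rng(10)
        perm = rng.permutation(sim.shape[0])
        labels1 = detect_subtypes(sim, seed=0)
        labels2 = detect_subtypes(sim[np.ix_(perm, perm)], seed=0)
        # same partition after undoing the permutation
        part1 = {tuple(sorted(np.nonzero(labels1 == c)[0])) for c in set(labels1)}
        back = np.empty_like(labels2)
        back[perm] = labels2
        part2 = {tuple(sorted(np.nonzero(back == c)[0])) for c in set(back)}
        assert part1 == part2

    def test_deterministic_given_seed(self):
        sim = self._planted(within=0.6, between=0.3)
        l1 = detect_subtypes(sim, seed=5)
        l2 = detect_subtypes(sim, seed=5)
        np.testing.assert_array_equal(l1, l2)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            detect_subtypes(np.empty((0, 0)))
        with pytest.raises(ValueError, match="symmetric"):
            detect_subtypes(np.array([[1.0, 0.1], [0.4, 1.0]]))


class TestRepresentativeGraph:
    def test_identical_cluster_picks_first(self):
        g = _g([("n1", "n2")])
        reps = representative_graph([g, g, g], [0, 0, 0])
        assert reps == {0: 0}

    def test_majority_member_wins(self):
        g = _g([("n1", "n2"), ("n2", "n3")])
        h = _g([("n3", "n4")])
        reps = representative_graph([g, g, h], [0, 0, 0])
        assert reps[0] in (0, 1)

    def test_singleton_cluster(self):
        g, h = _g([("n1", "n2")]), _g([("n3", "n4")])
        reps = representative_graph([g, h], [0, 1])
        assert reps == {0: 0, 1: 1}


class TestGraphCentrality:
    def test_complete_graph_betweenness_zero(self):
        nodes = ("a", "b", "c", "d")
        g = Microcircuit.from_edges(
            nodes, [(a, b) for i, a in enumerate(nodes) for b in nodes[i+1:]])
        assert graph_centrality(g, "betweenness") == 0.0

    def test_complete_graph_eigenvector_uniform(self):
        nodes = ("a", "b", "c", "d")
        g = Microcircuit.from_edges(
            nodes, [(a, b) for i, a in enumerate(nodes) for b in nodes[i+1:]])
        # all nodes equal by symmetry: mean = 1/sqrt(4)
        assert graph_centrality(g, "eigenvector") == pytest.approx(0.5)

    def test_path_betweenness_average(self):
        g = Microcircuit.from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert graph_centrality(g, "betweenness") == pytest.approx(1 / 3)

    def test_eigenvector_on_edgeless_graph_raises(self):
        with pytest.raises(ValueError, match="edgeless"):
            graph_centrality(Microcircuit(("a", "b")), "eigenvector")


class TestCompareSubtypes:
    def test_identical_groups(self):
        t, p = compare_subtypes([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                ["a", "a", "a", "b", "b", "b"])
        assert t == 0.0 and p == 1.0

    def test_fully_separated_constant_groups(self):
        t, p = compare_subtypes([0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                                ["a", "a", "a", "b", "b", "b"])
        assert abs(t) > 1e6 and p < 1e-10

    def test_hand_computed_pooled_t(self):
        # (1,2,3) vs (2,3,4): pooled var 1, t = -1 / sqrt(2/3)
        t, p = compare_subtypes([1, 2, 3, 2, 3, 4],
                                ["a", "a", "a", "b", "b", "b"])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        from scipy import stats as ss
        assert p == pytest.approx(2 * ss.t.sf(np.sqrt(1.5), df=4), abs=1e-12)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_subtypes([1, 2, 3], ["a", "a", "a"])


class TestMicrocircuitSubtyper:
    def test_fit_sets_attributes(self):
        g1 = _g([("n1", "n2")])
        g2 = _g([("n3", "n4")])
        st_ = MicrocircuitSubtyper(random_state=1).fit([g1, g1, g2, g2])
        assert st_.similarity_.shape == (4, 4)
        assert len(st_.labels_) == 4
        assert st_.n_clusters_ == 2
        assert set(st_.representatives_) == set(st_.labels_.tolist())
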