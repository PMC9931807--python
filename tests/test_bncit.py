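"""Score functions and the leaf-node hill-climbing blanket search."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from bca.bncit import ScoreConfig, bdeu_family_score, bic_family_score, find_markov_blanket
from bca.graphical_models import DataMatrix


def bdeu_oracle(child, parents, ess):
    """Independent closed-form BDeu: explicit product of gamma ratios per
    parent configuration, evaluated directly from the Dirichlet-multinomial
    marginal likelihood."""
    child = np.asarray(child, dtype=int)
    parents = np.asarray(parents, dtype=int)
    p = parents.shape[1] if parents.ndim == 2 else 0
    q = 2 ** p
    a_jk = ess / (2 * q)
    a_j = ess / q
    total = 0.0
    for conf in itertools.product((0, 1), repeat=p):
        mask = np.ones(child.size, dtype=bool)
        for k, v in enumerate(conf):
            mask &= parents[:, k] == v
        n1 = int(child[mask].sum())
        n0 = int(mask.sum()) - n1
        if n0 + n1 == 0:
            continue
        total += (gammaln(a_j) - gammaln(a_j + n0 + n1)
                  + gammaln(a_jk + n1) - gammaln(a_jk)
                  + gammaln(a_jk + n0) - gammaln(a_jk))
    return total


class TestBdeuScore:
    def test_closed_form_no_parents(self):
        # child (1,1,0,1), ess=1: log[G(1)/G(5) * G(.5+3)G(.5+1)/(G(.5)G(.5))]
        child = np.array([1.0, 1.0, 0.0, 1.0])
        expected = (gammaln(1.0) - gammaln(5.0)
                    + gammaln(0.5 + 3) + gammaln(0.5 + 1) - 2 * gammaln(0.5))
        assert bdeu_family_score(child, ess=1.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("ess", [0.5, 1.0, 4.0])
    @pytest.mark.parametrize("n_parents", [0, 1, 2, 3])
    def test_matches_gamma_oracle(self, ess, n_parents):
        rng = np.random.default_rng(n_parents * 10 + 1)
        child = rng.integers(0, 2, 60).astype(float)
        parents = rng.integers(0, 2, (60, n_parents)).astype(float)
        assert bdeu_family_score(child, parents, ess=ess) == pytest.approx(
            bdeu_oracle(child, parents, ess), abs=1e-9)

    def test_likelihood_equivalence(self):
        """score(X|Y) + score(Y) == score(Y|X) + score(X) for BDeu."""
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 200).astype(float)
        y = rng.integers(0, 2, 200).astype(float)
        lhs = bdeu_family_score(x, y[:, None]) + bdeu_family_score(y)
        rhs = bdeu_family_score(y, x[:, None]) + bdeu_family_score(x)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_decomposability_three_nodes(self):
        """Changing one family changes the summed network score by exactly
        that family's contribution (the score is decomposable)."""
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 100).astype(float)
        b = rng.integers(0, 2, 100).astype(float)
        c = ((a + b) % 2).astype(float)
        # network 1: a, b, c all parentless; network 2: c gains parents {a, b}
        net1 = (bdeu_family_score(a) + bdeu_family_score(b)
                + bdeu_family_score(c))
        net2 = (bdeu_family_score(a) + bdeu_family_score(b)
                + bdeu_family_score(c, np.column_stack([a, b])))
        assert net2 - net1 == pytest.approx(
            bdeu_family_score(c, np.column_stack([a, b]))
            - bdeu_family_score(c), abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        child = rng.integers(0, 2, 150).astype(float)
        parents = rng.integers(0, 2, (150, 2)).astype(float)
        perm = rng.permutation(150)
        assert bdeu_family_score(child, parents) == pytest.approx(
            bdeu_family_score(child[perm], parents[perm]), abs=1e-12)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bdeu_family_score(np.array([0.0, 2.0]))


class TestBicScore:
    def test_closed_form_no_parents(self):
        # child (0,1,2): sigma2_ML = 2/3, k = 2
        child = np.array([0.0, 1.0, 2.0])
        s2 = 2.0 / 3.0
        expected = -1.5 * math.log(2 * math.pi * s2) - 1.5 - math.log(3.0)
        assert bic_family_score(child) == pytest.approx(expected, abs=1e-12)

    def test_irrelevant_parent_penalized(self):
        rng = np.random.default_rng(0)
        child = rng.standard_normal(1000)
        noise = rng.standard_normal((1000, 1))
        assert bic_family_score(child) > bic_family_score(child, noise)

    def test_perfect_predictor_wins_with_variance_floor(self):
        child = np.linspace(-1, 1, 50)
        assert np.isfinite(bic_family_score(child, child[:, None]))
        assert bic_family_score(child, child[:, None]) > bic_family_score(child)

    def test_collinear_parents_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        child = x + 0.1 * rng.standard_normal(100)
        design = np.column_stack([x, x])  # duplicated column
        with pytest.warns(UserWarning, match="collinear"):
            score = bic_family_score(child, design)
        assert np.isfinite(score)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        child = rng.standard_normal(80)
        parents = rng.standard_normal((80, 2))
        perm = rng.permutation(80)
        assert bic_family_score(child, parents) == pytest.approx(
            bic_family_score(child[perm], parents[perm]), abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            bic_family_score(np.zeros(3), np.zeros((3, 2)))


class TestFindMarkovBlanket:
    def test_perfect_predictor_dominates(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 800).astype(float)
        noise = rng.integers(0, 2, (800, 2)).astype(float)
        d = DataMatrix(np.column_stack([a, a, noise]), "binary",
                       ("t", "copy", "n1", "n2"))
        mb = find_markov_blanket(d, "t", ScoreConfig())
        assert mb.members == frozenset({"copy"})

    def test_independent_columns_give_empty_blanket(self):
        rng = np.random.default_rng(6)
        d = DataMatrix(rng.integers(0, 2, (2000, 5)).astype(float), "binary",
                       tuple("abcde"))
        mb = find_markov_blanket(d, "c", ScoreConfig())
        assert mb.members == frozenset()

    def test_constant_target_warns_and_returns_empty(self):
        d = DataMatrix(np.column_stack([np.zeros(10), np.ones(10)]),
                       "binary", ("t", "o"))
        with pytest.warns(UserWarning, match="constant"):
            mb = find_markov_blanket(d, "t", ScoreConfig())
        assert mb.members == frozenset()

    def test_collider_blanket_of_c(self, collider_data):
        mb = find_markov_blanket(collider_data, "C", ScoreConfig())
        assert mb.members == frozenset({"A", "B", "D", "E"})

    def test_mode_mismatch_rejected(self, collider_data):
        with pytest.raises(ValueError, match="requires"):
            find_markov_blanket(collider_data, "C", ScoreConfig(score_type="bic"))

    def test_max_parents_cap(self, collider_data):
        mb = find_markov_blanket(collider_data, "C",
                                 ScoreConfig(max_parents=2))
        assert len(mb.members) <= 2

    def test_local_optimality_and_exhaustive_regret(self, collider_data):
        """The greedy blanket is locally optimal (no single move improves)
        and its score is compared against exhaustive enumeration of all
        parent subsets, the independent oracle for this search space."""
        data = collider_data
        target = "C"
        y = data.column(target)
        others = [l for l in data.node_labels if l != target]

        def score(subset):
            cols = np.column_stack([data.column(l) for l in subset]) \
                if subset else None
            return bdeu_family_score(y, cols, ess=1.0)

        mb = find_markov_blanket(data, target, ScoreConfig())
        found = sorted(mb.members)
        s_found = score(found)
        # local optimality: no single addition or removal improves
        for l in others:
            if l in mb.members:
                assert score(sorted(set(found) - {l})) <= s_found + 1e-9
            else:
                assert score(sorted(set(found) | {l})) <= s_found + 1e-9
        # exhaustive enumeration over all 2^4 subsets
        best = max(
            (score(sorted(s)) for r in range(len(others) + 1)
             for s in itertools.combinations(others, r)))
        regret = best - s_found
        assert regret <= 1e-9  # greedy finds the global optimum here

    def test_continuous_chain_blanket(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = 0.8 * x + 0.6 * rng.standard_normal(2000)
        z = 0.8 * y + 0.6 * rng.standard_normal(2000)
        d = DataMatrix(np.column_stack([x, y, z]), "continuous",
                       ("x", "y", "z"))
        mb = find_markov_blanket(d, "y", ScoreConfig(score_type="bic"))
        assert mb.members == frozenset({"x", "z"})
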