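"""Enrichment statistics against exhaustive enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from wes.weighting import (adjust_pvalues, binary_feature_pvalues,
                           compute_weights, continuous_feature_pvalues,
                           make_retrieval_objective, optimize_feature_count,
                           select_features)


def hypergeom_tail(k, M, K, n):
    """Exact P(X >= k) for X ~ Hypergeom(M, K, n), in rational arithmetic."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(M - K, n - j),
                          math.comb(M, n))
    return float(total)


def ranksum_two_sided(x, y):
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    m = n1 * (len(y))
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            count += 1
        total += 1
    return count / total


class TestFisherPvalues:
    def test_against_enumeration_small_tables(self, rng):
        # random set/background splits with n <= 30, exact to 1e-10
        for _ in range(60):
            M = int(rng.integers(8, 31))
            n_set = int(rng.integers(2, M - 1))
            col = rng.integers(0, 2, (M, 1))
            p = binary_feature_pvalues(col[:n_set], col,
                                       background_includes_set=True)[0]
            k = int(col[:n_set].sum())
            K = int(col.sum())
            expected = 1.0 if K == 0 else hypergeom_tail(k, M, K, n_set)
            assert p == pytest.approx(expected, abs=1e-10)

    def test_all_set_bits_on_worked_example(self):
        # 5-ligand set carries the only 5 occurrences among 100 molecules
        bg = np.zeros((100, 1), dtype=int)
        bg[:5] = 1
        p = binary_feature_pvalues(bg[:5], bg)[0]
        assert p == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_no_overrepresentation_gives_large_p(self):
        bg = np.zeros((40, 1), dtype=int)
        bg[::4] = 1          # same 25% frequency inside and outside the set
        p = binary_feature_pvalues(bg[:8], bg)[0]
        assert p >= 0.5

    def test_absent_bit_p_one(self):
        bg = np.zeros((20, 1), dtype=int)
        assert binary_feature_pvalues(bg[:5], bg)[0] == 1.0

    def test_empty_set_fatal(self):
        bg = np.ones((10, 2), dtype=int)
        with pytest.raises(ValueError):
            binary_feature_pvalues(bg[:0], bg)


class TestRanksumPvalues:
    def test_against_permutation_enumeration(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            x = rng.normal(size=(n1, 1))
            y = rng.normal(size=(n2, 1))
            p = continuous_feature_pvalues(x, y)[0]
            assert p == pytest.approx(ranksum_two_sided(x[:, 0], y[:, 0]),
                                      abs=1e-12)

    def test_complete_separation_example(self):
        x = np.array([[10.0], [11.0], [12.0]])
        y = np.array([[0.0], [1.0], [2.0]])
        # both extreme assignments out of C(6,3) = 20
        assert continuous_feature_pvalues(x, y)[0] == pytest.approx(2 / 20)

    def test_zero_variance_feature_p_one(self):
        x = np.full((4, 1), 3.0)
        y = np.full((6, 1), 3.0)
        assert continuous_feature_pvalues(x, y)[0] == 1.0

    def test_single_sample_warns_but_computes(self):
        with pytest.warns(UserWarning, match="low power"):
            p = continuous_feature_pvalues(np.array([[5.0]]),
                                           np.array([[0.0], [1.0], [2.0]]))
        assert 0 < p[0] <= 1


class TestBenjaminiHochberg:
    def test_direct_definition_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = adjust_pvalues(p)
            m = p.size
            order = np.argsort(p)
            expected = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m * p[i] / rank)
                expected[i] = running
            assert np.allclose(q, np.minimum(expected, 1.0), atol=1e-12)

    def test_hand_example(self):
        q = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_fixed_points(self):
        assert np.allclose(adjust_pvalues([0.2, 0.2, 0.2]), 0.2)
        assert adjust_pvalues([0.123])[0] == pytest.approx(0.123)


class TestWeights:
    def test_zero_at_and_above_threshold(self):
        w = compute_weights([0.05, 0.2, 1.0], q_threshold=0.05)
        assert (w == 0).all()

    def test_strictly_decreasing_below_threshold(self):
        w = compute_weights([0.001, 0.01, 0.049], q_threshold=0.05)
        assert w[0] > w[1] > w[2] > 0

    def test_all_insignificant_warns(self):
        with pytest.warns(UserWarning, match="all weights zero"):
            compute_weights([0.9, 0.5])


class TestSelection:
    def test_top_m_with_tie_rule(self):
        assert list(select_features([0, 3, 1, 3], 2)) == [1, 3]

    def test_m_equal_to_count(self):
        assert list(select_features([1.0, 2.0, 0.5], 3)) == [0, 1, 2]

    def test_all_zero_empty_selection(self):
        with pytest.warns(UserWarning, match="empty feature selection"):
            assert select_features([0.0, 0.0], 1).size == 0

    def test_shortfall_returns_nonzero_only(self):
        assert list(select_features([0.0, 2.0, 0.0, 1.0], 4)) == [1, 3]


class TestOptimizeFeatureCount:
    def test_constant_objective_smallest_m(self):
        assert optimize_feature_count([8, 2, 5], lambda m: 1.0) == 2

    def test_single_candidate(self):
        assert optimize_feature_count([7], lambda m: 0.3) == 7

    def test_all_failures_fatal(self):
        def boom(m):
            raise RuntimeError("nope")
        with pytest.raises(RuntimeError, match="every candidate"):
            optimize_feature_count([1, 2], boom)

    def test_planted_signature_recovery(self):
        # one ensemble with s = 10 signature bits out of 128
        rng = np.random.default_rng(42)
        s, B, n = 10, 128, 16
        sig = rng.choice(B, s, replace=False)
        p = np.full(B, 0.05)
        p[sig] = 0.7
        E = (rng.random((n, B)) < p).astype(int)
        Bg = (rng.random((300, B)) < 0.05).astype(int)
        pv = binary_feature_pvalues(E, Bg, background_includes_set=False)
        w = compute_weights(adjust_pvalues(pv))
        objective = make_retrieval_objective(E, Bg, w, rng=1)
        candidates = [5, 10, 15, 20, 40, 80, 128]
        m_star = optimize_feature_count(candidates, objective)
        assert s <= m_star <= 2 * s
        assert objective(m_star) >= objective(128)
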