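"""Statistical primitives versus brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecprograms.stats import (
    adjust_pvalues,
    hypergeom_two_sided_p,
    hypergeometric_overlap_test,
    mann_whitney_u,
    wilcoxon_signed_rank,
)


def hypergeom_pmf_exact(N, K, n, k) -> Fraction:
    """Exact hypergeometric pmf by binomial-coefficient arithmetic."""
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def two_sided_hypergeom_oracle(N, K, n, k) -> float:
    lo = max(0, K + n - N)
    hi = min(K, n)
    lower = sum(hypergeom_pmf_exact(N, K, n, j) for j in range(lo, k + 1))
    upper = sum(hypergeom_pmf_exact(N, K, n, j) for j in range(k, hi + 1))
    return float(min(1, 2 * min(lower, upper)))


def make_sets(N, K, n, k):
    """Gene sets over a universe of size N realizing overlap k."""
    universe = [f"g{i}" for i in range(N)]
    a = universe[:K]
    b = universe[:k] + universe[K : K + (n - k)]
    return a, b, universe


class TestHypergeometric:
    def test_forced_full_overlap_gives_p_one(self):
        a, b, universe = make_sets(20, 20, 5, 5)
        res = hypergeometric_overlap_test(a, b, universe)
        assert res.statistic == 5
        assert res.p_value == 1.0

    def test_hand_enumerated_case(self):
        # N=10, K=5, n=4, overlap 4: upper tail C(5,4)C(5,0)/C(10,4) = 5/210
        a, b, universe = make_sets(10, 5, 4, 4)
        res = hypergeometric_overlap_test(a, b, universe)
        assert res.p_value == pytest.approx(10 / 210, abs=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(40, 10, 10, 2), (30, 12, 7, 5), (60, 25, 25, 4)])
    def test_matches_exact_enumeration(self, N, K, n, k):
        a, b, universe = make_sets(N, K, n, k)
        res = hypergeometric_overlap_test(a, b, universe)
        assert res.p_value == pytest.approx(two_sided_hypergeom_oracle(N, K, n, k), abs=1e-12)

    def test_pmf_sums_to_one_small_universes(self):
        rng = np.random.default_rng(0)
        for N in range(2, 61, 7):
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            total = sum(hypergeom_pmf_exact(N, K, n, j) for j in range(lo, hi + 1))
            assert total == 1  # exact rational arithmetic

    def test_errors(self):
        with pytest.raises(ValueError, match="absent from the universe"):
            hypergeometric_overlap_test(["x"], ["g0"], ["g0", "g1"])
        with pytest.raises(ValueError, match="nonempty"):
            hypergeometric_overlap_test([], ["g0"], ["g0"])
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_overlap_test(["g0"], ["g0"], [])


def mwu_enumeration_oracle(x, y):
    """Two-sided exact p by enumerating all group labelings of the ranks."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mean_u) >= dev - 1e-12
        total += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p_value == pytest.approx(2 / 70, abs=1e-15)
        assert res.statistic == 0.0

    def test_complete_ties_degenerate(self):
        res = mann_whitney_u([3, 3, 3], [3, 3, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_exact_branch_equals_enumeration_all_partitions(self):
        rng = np.random.default_rng(1)
        for n1 in range(1, 9):
            for n2 in range(1, 11 - n1):
                data = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = data[:n1], data[n1:]
                assert mann_whitney_u(x, y).p_value == pytest.approx(
                    mwu_enumeration_oracle(x, y), abs=1e-12
                )

    def test_exact_branch_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mann_whitney_u(x, y).p_value == pytest.approx(expected, abs=1e-12)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            rejections += mann_whitney_u(x, y).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_symmetry_and_errors(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 3.0, 9.0, 0.5]
        assert mann_whitney_u(x, y).p_value == pytest.approx(mann_whitney_u(y, x).p_value)
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxonSignedRank:
    def test_identical_pairs(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank(np.zeros(5), [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(2 / 32, abs=1e-15)

    def test_exact_branch_matches_scipy(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            before = rng.normal(size=n)
            after = before + rng.normal(size=n)
            expected = wilcoxon(after - before, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_signed_rank(before, after).p_value == pytest.approx(expected, abs=1e-12)

    def test_shifted_pairs_detected(self):
        rng = np.random.default_rng(5)
        before = rng.normal(size=24)
        after = before + 1.0 + rng.normal(0, 0.8, size=24)
        assert wilcoxon_signed_rank(before, after).p_value < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


def bh_stepup_oracle(p):
    """BH adjusted p-values straight from the step-up definition."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestAdjustPvalues:
    def test_single_value(self):
        for proc in ("benjamini_hochberg", "bonferroni"):
            assert adjust_pvalues([0.5], procedure=proc).adjusted[0] == 0.5

    def test_hand_worked_bh(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.5]).adjusted
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_tied_inputs_collapse(self):
        adj = adjust_pvalues([0.2] * 7).adjusted
        assert np.allclose(adj, 0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(
                adjust_pvalues(p).adjusted, multipletests(p, method="fdr_bh")[1]
            )
            assert np.allclose(
                adjust_pvalues(p, procedure="bonferroni").adjusted,
                multipletests(p, method="bonferroni")[1],
            )

    def test_matches_stepup_definition(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 25))
            assert np.allclose(adjust_pvalues(p).adjusted, bh_stepup_oracle(p))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_order_invariance_and_bounds(self, p, rnd):
        p = np.asarray(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        direct = adjust_pvalues(p[perm]).adjusted
        permuted = adjust_pvalues(p).adjusted[perm]
        assert np.allclose(direct, permuted)
        assert (direct >= p[perm] - 1e-15).all()
        assert (direct <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2])


def test_vectorized_two_sided_helper_agrees_with_oracle():
    rng = np.random.default_rng(8)
    for _ in range(200):
        N = int(rng.integers(2, 61))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        lo, hi = max(0, K + n - N), min(K, n)
        k = int(rng.integers(lo, hi + 1))
        assert hypergeom_two_sided_p(N, K, n, k) == pytest.approx(
            two_sided_hypergeom_oracle(N, K, n, k), abs=1e-12
        )
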