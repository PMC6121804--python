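"""Statistical primitives against independent enumeration/brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from haplosel import stats

# ---------------------------------------------------------------------------
# oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Literal BH definition: sort, p*m/rank, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def fisher_oracle(table):
    """Two-tailed Fisher p by full enumeration over tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left = x) hypergeometric
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def wilcoxon_exact_oracle(diffs):
    """Two-tailed signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    dev = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            stats.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @pytest.mark.parametrize("p", [[1.0, 1.0, 1.0], [0.2], [0.5, 0.01, 0.9, 0.04]])
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(stats.bh_adjust(p), bh_oracle(p))

    def test_random_vectors_match_brute_force(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(stats.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.random(200)
        adj = stats.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            stats.bh_adjust([])


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_symmetric_tables(self):
        assert stats.fisher_exact_2x2([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)
        res = stats.fisher_exact_2x2([[2, 0], [0, 2]])
        assert res.p_value == pytest.approx(1 / 3)

    def test_imbalanced_table_vs_enumeration(self):
        table = [[1, 9], [11, 3]]
        res = stats.fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(fisher_oracle(table), rel=1e-9)
        assert res.p_value == pytest.approx(0.0028, abs=2e-4)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum() > 40:
                continue
            res = stats.fisher_exact_2x2(t)
            assert res.p_value == pytest.approx(fisher_oracle(t.tolist()), rel=1e-9)

    def test_doubling_cells_never_increases_p(self, rng):
        for _ in range(30):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            p1 = fisher_oracle(t.tolist())
            p2 = fisher_oracle((2 * t).tolist())
            assert p2 <= p1 + 1e-9

    def test_zero_margin_gives_finite_p(self):
        res = stats.fisher_exact_2x2([[5, 0], [2, 0]])
        assert 0 <= res.p_value <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[0, 0], [0, 0]])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_six_positive_differences(self):
        res = stats.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.z > 0

    def test_antisymmetry(self, rng):
        d = rng.normal(size=30)
        a = stats.wilcoxon_signed_rank(d)
        b = stats.wilcoxon_signed_rank(-d)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_all_zero_differences(self):
        res = stats.wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_value == 1.0 and res.n == 0

    def test_exact_matches_sign_enumeration(self, rng):
        for _ in range(10):
            d = rng.normal(size=10)
            res = stats.wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(wilcoxon_exact_oracle(d), rel=1e-9)

    def test_approx_close_to_exact_at_n20(self, rng):
        worst = 0.0
        for _ in range(100):
            d = rng.normal(size=20)
            exact = stats.wilcoxon_signed_rank(d).p_value  # exact path (n<=25)
            ranks = sps.rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            mu, sig = 20 * 21 / 4, math.sqrt(20 * 21 * 41 / 24)
            z = (w - mu - 0.5 * np.sign(w - mu)) / sig
            approx = min(1.0, 2 * sps.norm.sf(abs(z)))
            worst = max(worst, abs(exact - approx))
        assert worst < 0.01


# ---------------------------------------------------------------------------
# Welch t and Cohen's D
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_groups(self):
        res = stats.welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p_value == 1.0
        assert stats.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_example(self):
        # a=(1,2,3), b=(2,3,4): means 2 and 3, both variances 1
        # t = -1 / sqrt(1/3 + 1/3) = -1.224744871, df = 4 (equal variances)
        res = stats.welch_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5))
        assert res.df == pytest.approx(4.0)
        assert stats.cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_p_matches_t_cdf(self, rng):
        a, b = rng.normal(size=7), rng.normal(1.0, 2.0, size=12)
        res = stats.welch_t(a, b)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(res.t), res.df), abs=1e-10)

    def test_zero_variance_equal_means(self):
        res = stats.welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_separated_normals_recover_effect_size(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        d = stats.cohens_d(a, b)
        assert -1.3 < d < -0.7
        assert stats.welch_t(a, b).p_value < 1e-6


# ---------------------------------------------------------------------------
# Fisher's combined probability and binomial test
# ---------------------------------------------------------------------------

class TestFisherCombine:
    def test_all_ones(self):
        assert stats.fisher_combine([1.0, 1.0]).p_value == pytest.approx(1.0)

    def test_two_nominal_pvalues(self):
        res = stats.fisher_combine([0.05, 0.05])
        assert res.statistic == pytest.approx(-2 * 2 * np.log(0.05), rel=1e-12)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0175, abs=2e-4)

    def test_single_p_identity(self):
        assert stats.fisher_combine([0.123]).p_value == pytest.approx(0.123, rel=1e-12)

    def test_matches_chi2_tail_exactly(self, rng):
        p = rng.random(7)
        res = stats.fisher_combine(p)
        expected = sps.chi2.sf(-2 * np.log(p).sum(), 2 * len(p))
        assert abs(res.p_value - expected) < 1e-12

    def test_null_uniformity(self, rng):
        combined = [
            stats.fisher_combine(rng.random(4)).p_value for _ in range(2000)
        ]
        assert sps.kstest(combined, "uniform").pvalue > 0.01

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            res = stats.fisher_combine([0.0, 0.5])
        assert 0 <= res.p_value <= 1


class TestBinomTwoSided:
    def test_balanced(self):
        assert stats.binom_two_sided(10, 20) == pytest.approx(1.0)

    def test_extreme(self):
        assert stats.binom_two_sided(16, 16) == pytest.approx(2.0 ** -15)

    def test_matches_scipy_binomtest(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            expected = sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue
            assert stats.binom_two_sided(k, n) == pytest.approx(expected, rel=1e-9)
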