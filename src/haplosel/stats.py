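"""Shared statistical primitives.

Every test here is two-tailed. Conventions that differ between common
implementations are pinned down in one place so the rest of the pipeline
never has to think about them:

* Fisher's exact test uses the "sum of small p's" two-tailed rule: the
  p-value is the total hypergeometric probability of all tables (with the
  observed margins) whose probability does not exceed the observed table's.
  The reported odds ratio is the unconditional sample odds ratio ``ad/bc``.
* Cohen's D is ``(mean_a - mean_b) / pooled SD`` with ``n - 1`` weights,
  so the sign follows the first argument.
* The Wilcoxon signed-rank test drops zero differences, uses the exact
  null distribution for n <= 25 when there are no ties in ``|d|``, and a
  normal approximation with tie and continuity corrections otherwise. The
  reported Z is always the (signed) normal-approximation statistic so that
  its sign carries the direction of the shift.
* Fisher's combined probability is the chi-square tail of -2*sum(ln p) on
  2k degrees of freedom; a single p-value passes through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "fisher_exact_2x2",
    "wilcoxon_signed_rank",
    "welch_t",
    "cohens_d",
    "fisher_combine",
    "binom_two_sided",
    "FisherExactResult",
    "WilcoxonResult",
    "WelchResult",
    "CombinedPResult",
]

_TINY = np.nextafter(0.0, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-preserving.

    ``adjusted[i] = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j)`` capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class FisherExactResult:
    odds_ratio: float
    p_value: float


def fisher_exact_2x2(table) -> FisherExactResult:
    """Two-tailed Fisher's exact test on a 2x2 table of counts."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be nonnegative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = sps.fisher_exact(t.astype(np.int64), alternative="two-sided")
    return FisherExactResult(odds_ratio=float(odds), p_value=float(p))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    z: float
    p_value: float
    n: int  # nonzero differences used


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; if nothing remains the result is p = 1, z = 0.
    """
    d = np.asarray(differences, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(statistic=0.0, z=0.0, p_value=1.0, n=0)

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts).sum()) / 48.0
    )
    diff = w_plus - mu
    if sigma2 <= 0:
        z = 0.0
    else:
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)

    if n <= 25:
        p = _wilcoxon_exact_two_sided(ranks, w_plus)
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, z=float(z), p_value=p, n=n)


def _wilcoxon_exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Exact sign-flip null of W+ (mid-ranks allowed) via subset-sum counting.

    Doubling the ranks makes mid-ranks integral; the null assigns each of
    the 2^n sign patterns equal probability, and the two-sided p is the
    probability of a W+ at least as far from its mean as observed.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    mu = total / 2.0
    dev = abs(2.0 * w_plus - mu)
    support = np.arange(total + 1)
    return float(min(1.0, counts[np.abs(support - mu) >= dev - 1e-9].sum()))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t(a, b) -> WelchResult:
    """Welch two-sample t-test (Satterthwaite df), two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p_value=1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(t=float(t), df=float(a.size + b.size - 2), p_value=0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def cohens_d(a, b) -> float:
    """Cohen's D = (mean_a - mean_b) / pooled SD (n-1 weights)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    delta = a.mean() - b.mean()
    if pooled_var == 0:
        return 0.0 if delta == 0 else float(np.sign(delta) * np.inf)
    return float(delta / np.sqrt(pooled_var))


@dataclass(frozen=True)
class CombinedPResult:
    statistic: float  # -2 * sum(ln p)
    df: int
    p_value: float


def fisher_combine(pvalues) -> CombinedPResult:
    """Fisher's combined probability: X^2 = -2*sum(ln p) ~ chi2(2k)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, _TINY)
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedPResult(statistic=stat, df=df, p_value=float(sps.chi2.sf(stat, df)))


def binom_two_sided(k, n) -> np.ndarray:
    """Exact two-tailed binomial p-value(s) against p = 1/2, vectorized.

    With a symmetric null the sum-of-small-probabilities convention reduces
    to doubling the smaller tail (capped at 1). n = 0 gives p = 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(k < 0) or np.any(n < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(n == 0, 1.0, p)
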