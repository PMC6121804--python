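"""Expression quantification, active-transcription calling, and NB differential expression.

Normalization follows the median-of-ratios construction: each sample's
size factor is the median, over genes with nonzero counts in every
sample, of the ratio of its count to the gene's geometric mean; factors
are rescaled to geometric mean 1. FPKM is the conventional
``count * 1e9 / (length_bp * library_total)`` on raw totals, and a gene
is called actively transcribed in a tissue when its mean FPKM across
that tissue's samples strictly exceeds the cutoff (default 0.3).

Differential expression between two tissues is a negative-binomial Wald
test: per-gene method-of-moments dispersion on size-factor-normalized
counts, shrunk halfway toward the across-gene median (two or three
replicates make the raw estimate unstable), a delta-method standard
error of the log2 ratio of group means, and a moderated-t reference:
residual degrees of freedom ``n_a + n_b - 2`` plus prior degrees of
freedom equal to the residual df, mirroring the half-and-half shrinkage
of the dispersion toward its stable across-gene prior. (A plain normal
reference is anticonservative with 2-3 replicates; a plain t on the
residual df alone discards the precision the prior contributes and
loses most of the power.) The contract of this test is
calibration (type-I error and FDR control), not numerical parity with
any external DE package. P-values are BH-adjusted across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "size_factors",
    "fpkm",
    "active_transcription",
    "normalized_counts",
    "differential_expression",
]

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1."""
    c = counts.to_numpy(dtype=float)
    if c.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "needs a common reference (consider a pseudo-reference fallback)"
        )
    logc = np.log(c[all_nonzero])
    log_geo_mean = logc.mean(axis=1, keepdims=True)
    log_factors = np.median(logc - log_geo_mean, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns)


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def fpkm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads, on raw library totals."""
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero total reads in sample(s): {bad}")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def active_transcription(
    fpkm_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    threshold: float = 0.3,
) -> pd.Series:
    """Genes whose mean FPKM in a tissue strictly exceeds the cutoff."""
    samples = meta.loc[meta["tissue"] == tissue, "sample"]
    if samples.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    return fpkm_matrix[list(samples)].mean(axis=1) > threshold


def _group_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Raw per-gene MoM dispersion pooled over groups with >= 2 replicates."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = idx.size - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, np.nan)
        ok = np.isfinite(a)
        num[ok] += w * a[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    shrink_weight: float = 0.5,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """NB Wald test of log2(tissue_a / tissue_b) != 0 per gene.

    Returns a DataFrame indexed like ``counts`` with columns
    ``log2_fold_change, p_value, p_adjusted, bias_class`` where
    bias_class is ``{tissue_a}_biased`` / ``{tissue_b}_biased`` when
    ``p_adjusted < alpha`` (sign of the LFC), else ``unbiased``. Genes
    with zero counts in both groups get p = 1 and LFC = 0.
    """
    samples_a = meta.loc[meta["tissue"] == tissue_a, "sample"].tolist()
    samples_b = meta.loc[meta["tissue"] == tissue_b, "sample"].tolist()
    if not samples_a or not samples_b:
        raise ValueError(f"a tissue has zero samples: {tissue_a!r} vs {tissue_b!r}")

    sub = counts[samples_a + samples_b]
    factors = size_factors(sub)
    norm = (sub / factors).to_numpy(dtype=float)
    na, nb = len(samples_a), len(samples_b)
    ia = np.arange(na)
    ib = np.arange(na, na + nb)

    m_a = norm[:, ia].mean(axis=1)
    m_b = norm[:, ib].mean(axis=1)

    alpha_raw = _group_dispersion(norm, [ia, ib])
    valid = np.isfinite(alpha_raw)
    prior = float(np.median(alpha_raw[valid])) if valid.any() else 0.0
    disp = np.where(valid, alpha_raw, prior)
    disp = shrink_weight * prior + (1.0 - shrink_weight) * disp
    disp = np.maximum(disp, min_dispersion)

    lfc = np.log2((m_a + pseudocount) / (m_b + pseudocount))
    var_a = (m_a + disp * m_a**2) / na
    var_b = (m_b + disp * m_b**2) / nb
    se2 = (var_a / (m_a + pseudocount) ** 2 + var_b / (m_b + pseudocount) ** 2) / LN2**2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    # moderated df: residual + prior, prior df = residual df (shrink 1:1)
    df_resid = na + nb - 2
    df = df_resid + round(df_resid * shrink_weight / max(1.0 - shrink_weight, 1e-12))
    p = 2.0 * sps.t.sf(np.abs(stat), df=max(df, 1))

    both_zero = (m_a == 0) & (m_b == 0)
    lfc[both_zero] = 0.0
    p[both_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)

    padj = bh_adjust(p)
    bias = np.full(len(p), "unbiased", dtype=object)
    sig = padj < alpha
    bias[sig & (lfc > 0)] = f"{tissue_a}_biased"
    bias[sig & (lfc < 0)] = f"{tissue_b}_biased"

    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjusted": padj,
            "bias_class": bias,
        },
        index=counts.index,
    )
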