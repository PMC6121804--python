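"""Autosomal-normalized expression bias and cross-species ortholog contrasts.

Because the fraction of sex-linked genes differs between genomes, raw
between-tissue expression ratios are not comparable across species. The
correction normalizes every gene's bias by the average autosomal bias:

    x_bar = 2 ** mean_{autosomal g} [ log2(n1_g / n2_g) ]        (geometric mean)
    corrected_bias_g = log2( (n1_g / n2_g) / x_bar )

where n1, n2 are size-factor-normalized counts averaged across the
replicates of the two tissues (pseudocount added before ratios). An
algebraic consequence used as a self-check everywhere: corrected bias
equals the raw log2 ratio minus the mean raw log2 ratio of autosomal
genes, so the corrected autosomal mean is exactly zero.

The overline in the x_bar definition is read as the mean of log2 ratios
(geometric mean of ratios): the arithmetic-mean reading would leave the
corrected autosomal mean nonzero, defeating the correction's purpose.

Group contrasts: Fisher's exact enrichment of a focal bias class among
differentially expressed genes of two groups; a paired Wilcoxon
signed-rank test of corrected bias for XY genes against their autosomal
orthologs in the sister species (positive differences = greater pollen
bias in XY genes when tissue2 is pollen); and a Welch t plus Cohen's D
comparison of pollen FPKM between hemizygous and XY genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "ContrastResult",
    "autosomal_mean_bias",
    "corrected_bias",
    "make_bias_table",
    "ortholog_shift_test",
    "enrichment_fisher",
    "hemizygous_vs_xy_pollen",
]

log = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    """One group contrast: either a 2x2 count test or a continuous test."""

    name: str
    p_value: float
    statistic: float | None = None
    effect_size: float | None = None
    odds_ratio: float | None = None
    table: list | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "contrast": self.name,
            "p_value": self.p_value,
            "statistic": self.statistic,
            "effect_size": self.effect_size,
            "odds_ratio": self.odds_ratio,
            "n": self.n,
        }
        if self.table is not None:
            flat = np.asarray(self.table).ravel()
            row.update({f"table_{k}": int(v) for k, v in zip("abcd", flat)})
        row.update(self.extra)
        return row


def autosomal_mean_bias(n1, n2, pseudocount: float = 0.5) -> float:
    """Geometric-mean autosomal expression ratio x_bar between two tissues."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if n1.size == 0:
        raise ValueError("empty autosomal gene set")
    ratios = np.log2((n1 + pseudocount) / (n2 + pseudocount))
    if np.any(~np.isfinite(ratios)):
        raise ValueError("non-finite autosomal ratio (check pseudocount)")
    return float(2.0 ** ratios.mean())


def corrected_bias(n1, n2, x_bar: float, pseudocount: float = 0.5) -> np.ndarray:
    """Per-gene log2 tissue ratio corrected by the autosomal mean bias."""
    if x_bar <= 0:
        raise ValueError("x_bar must be positive")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    return np.log2(((n1 + pseudocount) / (n2 + pseudocount)) / x_bar)


def make_bias_table(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    classes: pd.Series,
    tissue1: str,
    tissue2: str,
    pseudocount: float = 0.5,
    autosomal_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Raw and autosomal-corrected per-gene bias between two tissues.

    ``norm_counts`` are size-factor-normalized counts (genes x samples);
    replicates are averaged within tissue before the ratio. ``classes``
    maps gene -> {autosomal, XY, hemizygous, ...}; ``autosomal_mask``
    optionally restricts the autosomal reference set (e.g. to genes
    passing the active-transcription filter in both tissues).

    Returns a DataFrame (raw_bias, corrected_bias, class) with the scalar
    x_bar stored in ``.attrs["x_bar"]``.
    """
    s1 = meta.loc[meta["tissue"] == tissue1, "sample"].tolist()
    s2 = meta.loc[meta["tissue"] == tissue2, "sample"].tolist()
    if not s1 or not s2:
        raise ValueError("both tissues need at least one sample")
    n1 = norm_counts[s1].mean(axis=1)
    n2 = norm_counts[s2].mean(axis=1)
    cls = classes.reindex(norm_counts.index)

    auto = cls == "autosomal"
    if autosomal_mask is not None:
        auto &= autosomal_mask.reindex(norm_counts.index).fillna(False)
    x_bar = autosomal_mean_bias(n1[auto], n2[auto], pseudocount)

    raw = np.log2((n1 + pseudocount) / (n2 + pseudocount))
    table = pd.DataFrame(
        {
            "raw_bias": raw,
            "corrected_bias": corrected_bias(n1, n2, x_bar, pseudocount),
            "class": cls,
        },
        index=norm_counts.index,
    )
    table.attrs["x_bar"] = x_bar
    return table


def ortholog_shift_test(
    bias_xy: pd.Series, bias_ortholog: pd.Series, name: str = "ortholog_shift"
) -> ContrastResult:
    """Paired Wilcoxon signed-rank of corrected bias: XY genes minus orthologs.

    The two series are aligned on their index (ortholog pair id); unpaired
    entries are dropped (logged). With the bias convention
    log2(tissue1/tissue2) and tissue2 = pollen, a *negative* median
    difference means greater pollen bias in XY genes; callers that want
    "positive = more pollen-biased" should pass biases with pollen as
    tissue1 or negate. The signed Z is reported so direction is explicit.
    """
    paired = pd.concat([bias_xy, bias_ortholog], axis=1, join="inner").dropna()
    dropped = max(len(bias_xy), len(bias_ortholog)) - len(paired)
    if dropped > 0:
        log.info("ortholog_shift_test: dropped %d unpaired genes", dropped)
    if len(paired) < 6:
        raise ValueError(f"need >= 6 ortholog pairs, got {len(paired)}")
    d = paired.iloc[:, 0] - paired.iloc[:, 1]
    res = stats.wilcoxon_signed_rank(d.to_numpy())
    return ContrastResult(
        name=name,
        p_value=res.p_value,
        statistic=res.z,
        effect_size=float(np.median(d)),
        n=len(paired),
        extra={"n_dropped": dropped, "w_plus": res.statistic},
    )


def enrichment_fisher(
    de: pd.DataFrame,
    genes_a,
    genes_b,
    focal_bias: str,
    name: str = "enrichment",
) -> ContrastResult:
    """Fisher's exact test: is the focal bias class enriched in group A?

    Restricted to differentially expressed genes (``bias_class`` not
    'unbiased'), the 2x2 table is group (A vs B) x bias (focal vs other).
    """
    genes_a = pd.Index(genes_a)
    genes_b = pd.Index(genes_b)
    if len(genes_a.intersection(genes_b)):
        raise ValueError("gene groups must be disjoint")
    de_sig = de[de["bias_class"] != "unbiased"]
    a = de_sig.loc[de_sig.index.intersection(genes_a), "bias_class"]
    b = de_sig.loc[de_sig.index.intersection(genes_b), "bias_class"]
    table = [
        [int((a == focal_bias).sum()), int((a != focal_bias).sum())],
        [int((b == focal_bias).sum()), int((b != focal_bias).sum())],
    ]
    res = stats.fisher_exact_2x2(table)
    return ContrastResult(
        name=name,
        p_value=res.p_value,
        odds_ratio=res.odds_ratio,
        table=table,
        n=int(np.sum(table)),
    )


def hemizygous_vs_xy_pollen(
    fpkm_hemizygous, fpkm_xy, name: str = "hemizygous_vs_xy_pollen"
) -> ContrastResult:
    """Welch t plus Cohen's D of pollen FPKM: hemizygous vs XY genes.

    A negative t / D means hemizygous genes are less pollen-expressed,
    the footprint of biased retention of pollen-expressed genes on the Y.
    """
    a = np.asarray(fpkm_hemizygous, dtype=float)
    b = np.asarray(fpkm_xy, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 genes in each class")
    res = stats.welch_t(a, b)
    return ContrastResult(
        name=name,
        p_value=res.p_value,
        statistic=res.t,
        effect_size=stats.cohens_d(a, b),
        n=int(a.size + b.size),
        extra={"df": res.df, "n_hemizygous": int(a.size), "n_xy": int(b.size)},
    )
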