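"""Allele-specific expression on sex-linked genes from high-confidence X/Y sites.

Reads aligned to a female (X) reference split each XY gene's expression
into reference (X) and alternate (Y) read counts at fixed X-Y difference
sites. Per site and sample, an exact two-tailed binomial test compares
the alt fraction against 1/2; per gene and sample the site p-values are
combined by Fisher's method (chi-square on 2k df), and the per-sample
gene p-values are combined the same way across a tissue's samples to
yield one p-value per gene. BH adjustment is applied across genes within
a tissue.

Direction is a second step, computed only for significant genes: the
mean over sites (counts pooled across the tissue's samples) of
log2((alt + pc)/(ref + pc)); positive means the Y copy is overexpressed.

Caveat: combining nearby sites by Fisher's method ignores read-level
dependence between sites covered by the same fragments and is therefore
anti-conservative under high overlap; the per-site read minimum and the
per-gene cap on sites (highest coverage first) mitigate this.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .biascompare import ContrastResult

__all__ = [
    "gene_ase_test",
    "combine_samples",
    "infer_direction",
    "analyze_tissue",
    "tissue_direction_contrast",
    "direction_fractions",
]

_TINY = np.nextafter(0.0, 1.0)


def gene_ase_test(
    ref_counts,
    alt_counts,
    min_reads_per_site: int = 8,
    max_sites: int = 20,
) -> float:
    """ASE p-value for one gene in one sample.

    Sites with fewer than ``min_reads_per_site`` total reads are dropped;
    at most ``max_sites`` sites (highest coverage first) enter Fisher's
    method. Returns NaN when no site qualifies (absence of evidence, not
    a p of 1).
    """
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    total = ref + alt
    keep = total >= min_reads_per_site
    if not keep.any():
        return float("nan")
    ref, alt, total = ref[keep], alt[keep], total[keep]
    if total.size > max_sites:
        order = np.argsort(-total, kind="stable")[:max_sites]
        alt, total = alt[order], total[order]
    p_sites = stats.binom_two_sided(alt, total)
    return stats.fisher_combine(p_sites).p_value


def combine_samples(pvalues) -> float:
    """Fisher's method across samples; a single p-value passes through."""
    return stats.fisher_combine(pvalues).p_value


def infer_direction(ref_by_site, alt_by_site, pseudocount: float = 0.5):
    """Mean per-site log2(alt/ref) and the implied overexpressed copy.

    Inputs are per-site counts already pooled across the tissue's
    samples. Returns ``(mean_log2_fc, direction)`` with direction
    'Y_over' for positive, 'X_over' for negative, 'none' for exactly 0.
    """
    ref = np.asarray(ref_by_site, dtype=float)
    alt = np.asarray(alt_by_site, dtype=float)
    if ref.size == 0:
        raise ValueError("no sites")
    lfc = float(np.mean(np.log2((alt + pseudocount) / (ref + pseudocount))))
    direction = "Y_over" if lfc > 0 else ("X_over" if lfc < 0 else "none")
    return lfc, direction


def analyze_tissue(
    allelic: pd.DataFrame,
    highconf_sites: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    alpha: float = 0.05,
    min_reads_per_site: int = 8,
    max_sites: int = 20,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene ASE calls for one tissue.

    ``allelic`` is the long table (gene_id, site_pos, sample, ref_count,
    alt_count); ``highconf_sites`` has (gene_id, pos) from the
    sex-linkage caller. Returns a DataFrame indexed by gene_id with
    ``n_samples, combined_p, p_adjusted, mean_log2_fc, direction``;
    direction is 'none' unless ``p_adjusted < alpha``.
    """
    samples = meta.loc[meta["tissue"] == tissue, "sample"]
    if samples.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = allelic[allelic["sample"].isin(set(samples))]
    sub = sub.merge(
        highconf_sites[["gene_id", "pos"]].rename(columns={"pos": "site_pos"}),
        on=["gene_id", "site_pos"],
    )
    if sub.empty:
        return pd.DataFrame(
            columns=["n_samples", "combined_p", "p_adjusted", "mean_log2_fc", "direction"]
        )

    sub = sub.assign(total=sub["ref_count"] + sub["alt_count"])
    qual = sub[sub["total"] >= min_reads_per_site]
    qual = (
        qual.sort_values("total", ascending=False, kind="stable")
        .groupby(["gene_id", "sample"], sort=False)
        .head(max_sites)
        .copy()
    )
    if qual.empty:
        return pd.DataFrame(
            columns=["n_samples", "combined_p", "p_adjusted", "mean_log2_fc", "direction"]
        )
    qual["p_site"] = np.maximum(
        stats.binom_two_sided(qual["alt_count"].to_numpy(), qual["total"].to_numpy()),
        _TINY,
    )
    qual["neg2ln"] = -2.0 * np.log(qual["p_site"])

    per_sample = qual.groupby(["gene_id", "sample"]).agg(
        stat=("neg2ln", "sum"), k=("neg2ln", "size")
    )
    per_sample["p"] = sps.chi2.sf(per_sample["stat"], 2 * per_sample["k"])
    per_sample["neg2ln"] = -2.0 * np.log(np.maximum(per_sample["p"], _TINY))

    per_gene = per_sample.groupby("gene_id").agg(
        stat=("neg2ln", "sum"), n_samples=("neg2ln", "size")
    )
    per_gene["combined_p"] = sps.chi2.sf(per_gene["stat"], 2 * per_gene["n_samples"])
    per_gene["p_adjusted"] = stats.bh_adjust(per_gene["combined_p"].to_numpy())

    # direction: pool counts per site across the tissue's samples
    pooled = sub.groupby(["gene_id", "site_pos"])[["ref_count", "alt_count"]].sum()
    pooled = pooled[(pooled["ref_count"] + pooled["alt_count"]) >= min_reads_per_site]
    lfc_site = np.log2(
        (pooled["alt_count"] + pseudocount) / (pooled["ref_count"] + pseudocount)
    )
    mean_lfc = lfc_site.groupby("gene_id").mean()

    out = per_gene[["n_samples", "combined_p", "p_adjusted"]].copy()
    out["mean_log2_fc"] = mean_lfc.reindex(out.index)
    sig = (out["p_adjusted"] < alpha) & out["mean_log2_fc"].notna()
    out["direction"] = "none"
    out.loc[sig & (out["mean_log2_fc"] > 0), "direction"] = "Y_over"
    out.loc[sig & (out["mean_log2_fc"] < 0), "direction"] = "X_over"
    return out.sort_index()


def tissue_direction_contrast(
    result_focal: pd.DataFrame,
    result_leaf: pd.DataFrame,
    name: str = "tissue_vs_leaf_direction",
) -> ContrastResult:
    """Fisher's exact test of (X_over, Y_over) counts: focal tissue vs leaf.

    Leaf counts serve as the null expectation; genes without significant
    allelic bias are excluded because the unbiased fraction depends on
    per-sample depth rather than biology.
    """
    f_x = int((result_focal["direction"] == "X_over").sum())
    f_y = int((result_focal["direction"] == "Y_over").sum())
    l_x = int((result_leaf["direction"] == "X_over").sum())
    l_y = int((result_leaf["direction"] == "Y_over").sum())
    if f_x + f_y == 0 or l_x + l_y == 0:
        raise ValueError(
            "no significantly direction-biased genes in one tissue; "
            "contrast is undefined"
        )
    table = [[f_x, f_y], [l_x, l_y]]
    res = stats.fisher_exact_2x2(table)
    return ContrastResult(
        name=name,
        p_value=res.p_value,
        odds_ratio=res.odds_ratio,
        table=table,
        n=f_x + f_y + l_x + l_y,
    )


def direction_fractions(result: pd.DataFrame) -> dict:
    """Percent of analyzed genes with X over-, Y over-, or no allelic bias."""
    n = len(result)
    if n == 0:
        return {"pct_X_over": 0.0, "pct_Y_over": 0.0, "pct_none": 0.0, "n_genes": 0}
    return {
        "pct_X_over": 100.0 * float((result["direction"] == "X_over").sum()) / n,
        "pct_Y_over": 100.0 * float((result["direction"] == "Y_over").sum()) / n,
        "pct_none": 100.0 * float((result["direction"] == "none").sum()) / n,
        "n_genes": n,
    }
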