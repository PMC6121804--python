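"""Sex-linkage classification from SNP segregation in sexed genotype panels.

In an XY system aligned against a female (X) reference, a fixed X-Y
difference shows a diagnostic segregation pattern in population data:
every female is homozygous reference and every male heterozygous. Sites
passing this rule (with minimum-call and missingness filters) form the
high-confidence list used for allele-specific expression. A family-based
alternative exists for species without population panels: the father is
heterozygous, the mother homozygous reference, and the paternal alternate
allele is transmitted to every son and no daughter.

Genes are then classified: *XY* if they carry sex-linked sites and the
alternate (Y) allele is seen in expression data; *hemizygous* if they
carry sex-linked sites but zero alternate reads (the Y copy is lost or
silenced — a proxy, since direct hemizygosity calling needs coverage
data); *autosomal* if no site shows sex-linked segregation; *ambiguous*
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "GenotypePanel",
    "call_fixed_xy_differences",
    "call_family_segregation",
    "classify_genes",
]

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


@dataclass
class GenotypePanel:
    """Diploid genotype codes for sexed individuals at gene-anchored sites.

    ``individuals``: DataFrame with columns ``individual`` and ``sex``
    ('M'/'F'). ``genotypes``: DataFrame indexed by (gene_id, pos) with one
    int8 column per individual, values in {0 hom_ref, 1 het, 2 hom_alt,
    -1 missing}.
    """

    individuals: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self):
        sexes = set(self.individuals["sex"])
        if not sexes <= {"M", "F"}:
            raise ValueError(f"unknown sex labels: {sexes - {'M', 'F'}}")
        if "M" not in sexes or "F" not in sexes:
            raise ValueError("panel needs at least one male and one female")
        missing_cols = set(self.individuals["individual"]) - set(self.genotypes.columns)
        if missing_cols:
            raise ValueError(f"individuals absent from genotype table: {missing_cols}")
        if self.genotypes.index.duplicated().any():
            raise ValueError("duplicate (gene_id, pos) sites in panel")

    def columns_by_sex(self, sex: str) -> list:
        return self.individuals.loc[self.individuals["sex"] == sex, "individual"].tolist()


def call_fixed_xy_differences(
    panel: GenotypePanel,
    min_males: int = 3,
    min_females: int = 3,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Sites where all called females are hom_ref and all called males het.

    A site qualifies iff, among non-missing calls, every female is
    homozygous reference and every male heterozygous, with at least
    ``min_males`` / ``min_females`` called individuals of each sex and a
    missing fraction of at most ``max_missing_frac``.

    Returns a DataFrame (gene_id, pos, n_males_called, n_females_called).
    """
    male_cols = panel.columns_by_sex("M")
    female_cols = panel.columns_by_sex("F")
    G = panel.genotypes
    if G.shape[0] == 0:
        return pd.DataFrame(columns=["gene_id", "pos", "n_males_called", "n_females_called"])

    M = G[male_cols].to_numpy()
    F = G[female_cols].to_numpy()
    m_called = (M != MISSING).sum(axis=1)
    f_called = (F != MISSING).sum(axis=1)
    if m_called.max(initial=0) == 0 or f_called.max(initial=0) == 0:
        warnings.warn("no called males or females at any site", stacklevel=2)
        return pd.DataFrame(columns=["gene_id", "pos", "n_males_called", "n_females_called"])

    males_ok = ((M == HET) | (M == MISSING)).all(axis=1) & (m_called >= min_males)
    females_ok = ((F == HOM_REF) | (F == MISSING)).all(axis=1) & (f_called >= min_females)
    n_ind = len(male_cols) + len(female_cols)
    n_missing = n_ind - (m_called + f_called)
    # integer comparison avoids float noise at the boundary
    keep = males_ok & females_ok & (n_missing <= max_missing_frac * n_ind + 1e-9)

    out = G.index.to_frame(index=False).rename(columns={"pos": "pos"})[keep]
    out = out.reset_index(drop=True)
    out["n_males_called"] = m_called[keep]
    out["n_females_called"] = f_called[keep]
    return out


def call_family_segregation(
    panel: GenotypePanel, father: str, mother: str
) -> pd.DataFrame:
    """Sites with Y-like transmission in a single sexed family.

    Accepts a site iff (over non-missing calls) the father is het, the
    mother hom_ref, every son het and every daughter hom_ref: the paternal
    alternate allele behaves as Y-transmitted. Parents must be present and
    called at a site for it to qualify.
    """
    for parent in (father, mother):
        if parent not in panel.genotypes.columns:
            raise ValueError(f"parent {parent!r} missing from panel")
    G = panel.genotypes
    progeny = panel.individuals[~panel.individuals["individual"].isin([father, mother])]
    son_cols = progeny.loc[progeny["sex"] == "M", "individual"].tolist()
    daughter_cols = progeny.loc[progeny["sex"] == "F", "individual"].tolist()

    fa = G[father].to_numpy()
    mo = G[mother].to_numpy()
    S = G[son_cols].to_numpy() if son_cols else np.empty((len(G), 0), dtype=np.int8)
    D = G[daughter_cols].to_numpy() if daughter_cols else np.empty((len(G), 0), dtype=np.int8)
    keep = (
        (fa == HET)
        & (mo == HOM_REF)
        & ((S == HET) | (S == MISSING)).all(axis=1)
        & ((D == HOM_REF) | (D == MISSING)).all(axis=1)
    )
    out = G.index.to_frame(index=False)[keep].reset_index(drop=True)
    out["n_sons_called"] = (S != MISSING).sum(axis=1)[keep] if son_cols else 0
    out["n_daughters_called"] = (D != MISSING).sum(axis=1)[keep] if daughter_cols else 0
    return out


def classify_genes(
    panel: GenotypePanel,
    accepted_sites: pd.DataFrame,
    allelic: pd.DataFrame,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Per-gene linkage calls from accepted sites plus Y-allele expression.

    * ``XY``: >= ``min_sites`` accepted sex-linked sites and at least one
      alternate (Y) read at those sites in the expression data;
    * ``hemizygous``: accepted sites but zero alternate reads anywhere —
      the Y copy is absent from expression;
    * ``autosomal``: no accepted site;
    * ``ambiguous``: accepted sites but no usable expression evidence, or
      fewer accepted sites than ``min_sites``.

    Returns a DataFrame (gene_id, called_class, n_fixed_diff_sites,
    n_xpoly_sites) covering every gene present in the panel;
    ``n_xpoly_sites`` counts the gene's panel sites that failed the
    sex-linked segregation rule.
    """
    all_genes = panel.genotypes.index.get_level_values("gene_id")
    sites_per_gene = pd.Series(all_genes).value_counts()
    n_accepted = (
        accepted_sites.groupby("gene_id").size()
        if len(accepted_sites)
        else pd.Series(dtype=int)
    )

    if len(accepted_sites) and len(allelic):
        acc = allelic.merge(
            accepted_sites[["gene_id", "pos"]].rename(columns={"pos": "site_pos"}),
            on=["gene_id", "site_pos"],
        )
        alt_sum = acc.groupby("gene_id")["alt_count"].sum()
        covered = acc.groupby("gene_id").size()
    else:
        alt_sum = pd.Series(dtype=int)
        covered = pd.Series(dtype=int)

    rows = []
    for gene in sites_per_gene.index:
        n_acc = int(n_accepted.get(gene, 0))
        n_total = int(sites_per_gene[gene])
        if n_acc == 0:
            called = "autosomal"
        elif n_acc < min_sites or covered.get(gene, 0) == 0:
            called = "ambiguous"
        elif alt_sum.get(gene, 0) > 0:
            called = "XY"
        else:
            called = "hemizygous"
        rows.append(
            {
                "gene_id": gene,
                "called_class": called,
                "n_fixed_diff_sites": n_acc,
                "n_xpoly_sites": n_total - n_acc,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
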