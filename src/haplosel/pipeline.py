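"""End-to-end orchestration: simulate -> linkage -> expression -> bias -> ASE -> contrasts.

:func:`analyze` runs every inference stage on an in-memory dataset and
returns all result tables plus a JSON-able summary; :func:`run_all`
additionally simulates the data and writes everything to a run
directory. Both are deterministic given the simulation seed. Each stage
is also exposed on its own so CLI subcommands and tests can run them in
isolation with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ase as ase_mod
from . import biascompare, expression, io, sexlinkage
from .simulate import SPECIES, SimConfig, simulate_dataset

log = logging.getLogger("haplosel")

__all__ = ["PipelineParams", "StageError", "analyze", "run_all"]


@dataclass
class PipelineParams:
    """Inference-side knobs, separate from the generative scenario."""

    alpha: float = 0.05
    fpkm_threshold: float = 0.3
    pseudocount: float = 0.5
    min_males: int = 3
    min_females: int = 3
    max_missing_frac: float = 0.2
    min_sites: int = 1
    min_reads_per_site: int = 8
    max_sites_per_gene: int = 20
    tissue_pairs: tuple = (("leaf", "pollen"), ("flower_bud", "pollen"))

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _try_contrast(res, name, fn):
    """Run a contrast; record it as skipped when undefined (e.g. empty table)."""
    try:
        res.contrasts.append(fn())
    except ValueError as why:
        res.skipped.append((name, str(why)))
        log.warning("skipped contrast %s: %s", name, why)


@dataclass
class PipelineResults:
    linkage: dict = field(default_factory=dict)          # species -> LinkageCall df
    highconf_sites: dict = field(default_factory=dict)   # species -> site df
    de: dict = field(default_factory=dict)               # (species, t1, t2) -> df
    bias: dict = field(default_factory=dict)             # (species, t1, t2) -> df
    fpkm: dict = field(default_factory=dict)             # species -> df
    ase: dict = field(default_factory=dict)              # (species, tissue) -> df
    contrasts: list = field(default_factory=list)        # ContrastResult
    skipped: list = field(default_factory=list)          # (name, reason)
    summary: dict = field(default_factory=dict)


def _species_view(dataset, sp):
    catalog = dataset.catalog[dataset.catalog["species"] == sp].set_index("gene_id")
    meta = dataset.meta[dataset.meta["species"] == sp]
    counts = dataset.counts.loc[catalog.index, meta["sample"].tolist()]
    return catalog, meta, counts


def run_linkage_stage(dataset, params: PipelineParams):
    linkage, highconf = {}, {}
    for sp, panel in dataset.panels.items():
        sites = sexlinkage.call_fixed_xy_differences(
            panel,
            min_males=params.min_males,
            min_females=params.min_females,
            max_missing_frac=params.max_missing_frac,
        )
        highconf[sp] = sites
        linkage[sp] = sexlinkage.classify_genes(
            panel, sites, dataset.allelic, min_sites=params.min_sites
        )
    return linkage, highconf


def analyze(dataset, params: PipelineParams | None = None) -> PipelineResults:
    """All inference stages on one simulated (or loaded) dataset."""
    params = params or PipelineParams()
    res = PipelineResults()

    # -- sex linkage -------------------------------------------------------
    try:
        res.linkage, res.highconf_sites = run_linkage_stage(dataset, params)
    except Exception as e:  # noqa: BLE001
        raise StageError("linkage", e) from e

    for sp in SPECIES:
        catalog, meta, counts = _species_view(dataset, sp)
        calls = res.linkage.get(sp)
        called = (
            calls.set_index("gene_id")["called_class"].reindex(catalog.index).fillna("autosomal")
            if calls is not None and len(calls)
            else pd.Series("autosomal", index=catalog.index)
        )
        xy_genes = called.index[called == "XY"]
        hemi_genes = called.index[called == "hemizygous"]
        auto_genes = called.index[called == "autosomal"]

        # -- expression ----------------------------------------------------
        try:
            factors = expression.size_factors(counts)
            norm = counts / factors
            fpkm = expression.fpkm(counts, catalog["length_bp"])
            res.fpkm[sp] = fpkm
            active = {
                t: expression.active_transcription(fpkm, meta, t, params.fpkm_threshold)
                for t in dataset.config.tissues
            }
            for t1, t2 in params.tissue_pairs:
                res.de[(sp, t1, t2)] = expression.differential_expression(
                    counts, meta, t1, t2, alpha=params.alpha, pseudocount=params.pseudocount
                )
        except Exception as e:  # noqa: BLE001
            raise StageError(f"expression[{sp}]", e) from e

        # -- bias tables and count contrasts -------------------------------
        try:
            for t1, t2 in params.tissue_pairs:
                mask = active[t1] & active[t2]
                res.bias[(sp, t1, t2)] = biascompare.make_bias_table(
                    norm, meta, called, t1, t2,
                    pseudocount=params.pseudocount, autosomal_mask=mask,
                )
                de = res.de[(sp, t1, t2)]
                focal = f"{t2}_biased"  # tissue2 is pollen by convention
                name = f"{sp}:{t1}_{t2}:xy_vs_autosomal_{focal}"
                _try_contrast(
                    res, name,
                    lambda de=de, n=name, f=focal: biascompare.enrichment_fisher(
                        de, xy_genes, auto_genes, f, name=n
                    ),
                )
                if len(hemi_genes) >= 1:
                    name = f"{sp}:{t1}_{t2}:hemizygous_vs_xy_{focal}"
                    _try_contrast(
                        res, name,
                        lambda de=de, n=name, f=focal: biascompare.enrichment_fisher(
                            de, hemi_genes, xy_genes, f, name=n
                        ),
                    )
            # pollen FPKM: hemizygous vs XY (biased-retention footprint)
            if "pollen" in dataset.config.tissues and len(hemi_genes) >= 2 and len(xy_genes) >= 2:
                pollen_samples = meta.loc[meta["tissue"] == "pollen", "sample"].tolist()
                pollen_fpkm = fpkm[pollen_samples].mean(axis=1)
                name = f"{sp}:hemizygous_vs_xy_pollen_fpkm"
                _try_contrast(
                    res, name,
                    lambda n=name: biascompare.hemizygous_vs_xy_pollen(
                        pollen_fpkm.loc[hemi_genes], pollen_fpkm.loc[xy_genes], name=n
                    ),
                )
        except Exception as e:  # noqa: BLE001
            raise StageError(f"bias[{sp}]", e) from e

        # -- allele-specific expression ------------------------------------
        try:
            sites = res.highconf_sites.get(sp, pd.DataFrame(columns=["gene_id", "pos"]))
            # ASE is defined on XY genes (both copies expressed); hemizygous
            # genes are trivially 100% X and would swamp the direction counts
            sites = sites[sites["gene_id"].isin(set(xy_genes))]
            for tissue in dataset.config.tissues:
                res.ase[(sp, tissue)] = ase_mod.analyze_tissue(
                    dataset.allelic, sites, meta, tissue,
                    alpha=params.alpha,
                    min_reads_per_site=params.min_reads_per_site,
                    max_sites=params.max_sites_per_gene,
                    pseudocount=params.pseudocount,
                )
            for tissue in dataset.config.tissues:
                if tissue == "leaf":
                    continue
                name = f"{sp}:ase_direction_{tissue}_vs_leaf"
                try:
                    res.contrasts.append(
                        ase_mod.tissue_direction_contrast(
                            res.ase[(sp, tissue)], res.ase[(sp, "leaf")], name=name
                        )
                    )
                except ValueError as why:
                    res.skipped.append((name, str(why)))
                    log.warning("skipped contrast %s: %s", name, why)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"ase[{sp}]", e) from e

    # -- cross-species ortholog shift --------------------------------------
    try:
        _ortholog_contrasts(dataset, params, res)
    except Exception as e:  # noqa: BLE001
        raise StageError("ortholog_shift", e) from e

    res.summary = _summarize(dataset, params, res)
    return res


def _ortholog_contrasts(dataset, params, res: PipelineResults):
    """XY genes in one species vs their autosomal orthologs in the other.

    Bias convention log2(t1/t2) with t2 = pollen: a negative shift (XY
    minus ortholog) means greater pollen bias in the XY genes.
    """
    cat = dataset.catalog.set_index("gene_id")
    for sp_xy, sp_ortho in ((SPECIES[0], SPECIES[1]), (SPECIES[1], SPECIES[0])):
        calls_xy = res.linkage.get(sp_xy)
        calls_o = res.linkage.get(sp_ortho)
        if calls_xy is None or calls_o is None:
            continue
        xy = set(calls_xy.loc[calls_xy["called_class"] == "XY", "gene_id"])
        auto_o = set(calls_o.loc[calls_o["called_class"] == "autosomal", "gene_id"])
        # genes never seen in the panel are autosomal by absence of evidence
        in_panel_o = set(calls_o["gene_id"])
        auto_o |= set(cat.index[cat["species"] == sp_ortho]) - in_panel_o
        for t1, t2 in params.tissue_pairs:
            bias_xy = res.bias[(sp_xy, t1, t2)]
            bias_o = res.bias[(sp_ortho, t1, t2)]
            bx = bias_xy.loc[bias_xy.index.isin(xy), "corrected_bias"]
            bx.index = cat.loc[bx.index, "ortholog_id"]
            bo = bias_o.loc[bias_o.index.isin(auto_o), "corrected_bias"]
            bo.index = cat.loc[bo.index, "ortholog_id"]
            name = f"{sp_xy}:{t1}_{t2}:xy_vs_ortholog_shift"
            try:
                res.contrasts.append(
                    biascompare.ortholog_shift_test(bx, bo.loc[bo.index.isin(bx.index)], name=name)
                )
            except ValueError as why:
                res.skipped.append((name, str(why)))


def _summarize(dataset, params, res: PipelineResults) -> dict:
    summary: dict = {"seed": dataset.config.seed, "n_genes": dataset.config.n_genes}
    for sp in SPECIES:
        calls = res.linkage.get(sp)
        if calls is not None and len(calls):
            counts = calls["called_class"].value_counts().to_dict()
        else:
            counts = {}
        summary[f"class_counts_{sp}"] = {k: int(v) for k, v in sorted(counts.items())}
        for (s, t1, t2), de in res.de.items():
            if s != sp:
                continue
            frac = de["bias_class"].value_counts(normalize=True).to_dict()
            summary[f"de_fractions_{sp}_{t1}_{t2}"] = {
                k: round(float(v), 6) for k, v in sorted(frac.items())
            }
        for (s, tissue), df in res.ase.items():
            if s != sp:
                continue
            summary[f"ase_fractions_{sp}_{tissue}"] = {
                k: round(float(v), 4) if isinstance(v, float) else v
                for k, v in ase_mod.direction_fractions(df).items()
            }
    summary["contrasts"] = {
        c.name: {
            "p_value": float(c.p_value),
            "statistic": None if c.statistic is None else float(c.statistic),
            "odds_ratio": None if c.odds_ratio is None else float(c.odds_ratio),
            "effect_size": None if c.effect_size is None else float(c.effect_size),
        }
        for c in res.contrasts
    }
    summary["skipped_contrasts"] = {name: why for name, why in res.skipped}
    return summary


def write_results(res: PipelineResults, outdir):
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, df in res.linkage.items():
        io.write_table(df, out / f"linkage_{sp}.tsv")
    for sp, df in res.highconf_sites.items():
        io.write_table(df, out / f"highconf_sites_{sp}.tsv")
    for (sp, t1, t2), df in res.de.items():
        io.write_table(df.reset_index(), out / f"de_{sp}_{t1}_{t2}.tsv")
    for (sp, t1, t2), df in res.bias.items():
        io.write_table(df.reset_index(), out / f"bias_{sp}_{t1}_{t2}.tsv")
    for (sp, tissue), df in res.ase.items():
        io.write_table(df.reset_index(), out / f"ase_{sp}_{tissue}.tsv")
    if res.contrasts:
        io.write_table(
            pd.DataFrame([c.to_row() for c in res.contrasts]), out / "contrasts.tsv"
        )
    fractions = [
        {"species": sp, "tissue": tissue, **ase_mod.direction_fractions(df)}
        for (sp, tissue), df in res.ase.items()
    ]
    if fractions:
        io.write_table(pd.DataFrame(fractions), out / "ase_fractions.tsv")
    (out / "summary.json").write_text(
        json.dumps(res.summary, indent=2, sort_keys=True) + "\n"
    )


def run_all(config: SimConfig, params: PipelineParams | None = None, outdir=None):
    """Simulate, analyze, and (optionally) write a full run directory."""
    params = params or PipelineParams()
    log.info("simulating dataset (seed=%d, n_genes=%d)", config.seed, config.n_genes)
    try:
        dataset = simulate_dataset(config)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    res = analyze(dataset, params)
    if outdir is not None:
        io.write_dataset(dataset, outdir)
        write_results(res, outdir)
    return dataset, res
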