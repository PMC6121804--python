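"""Synthetic two-species datasets for studying pollen selection on sex chromosomes.

The generator emulates the study design the pipeline is built for: two
dioecious plant species ("A" and "B") whose XY sex chromosomes evolved
independently, RNA-seq counts from male leaf, flower-bud and pollen tissue,
a sexed population genotype panel carrying fixed X-Y SNP differences plus
X-polymorphism decoys, and per-site allelic (X vs Y) read counts.

Three evolutionary processes are parameterized so each downstream stage has
a recoverable ground truth:

* **pollen bias** — a fraction of genes is upregulated in pollen
  (``pollen_bias_lfc``), shared across the two species (ancestral state);
* **biased retention** — the probability that a sex-linked gene is
  hemizygous (lost/silenced Y expression) follows a logistic function of
  its standardized pollen expression, so a negative slope preferentially
  retains pollen-expressed genes on the Y;
* **pollenization** — a fraction of XY genes gets an extra log2 fold change
  on the Y-allele component in pollen only.

Counts are negative binomial with ``var = mu + dispersion * mu**2`` and a
dispersion shared across genes. XY gene totals are the sum of an X and a Y
component; hemizygous genes express their full mean from the X copy alone
(dosage compensation), so retention bias — not dosage — is the recoverable
signal. Each generator call draws from its own RNG stream seeded from
``(seed, stage offset)`` so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .sexlinkage import HET, HOM_REF, GenotypePanel

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "generate_catalog",
    "simulate_counts",
    "simulate_genotypes_and_allelic_counts",
    "simulate_dataset",
    "null_scenario",
    "biased_retention_scenario",
    "pollenization_scenario",
]

SPECIES = ("A", "B")
DEFAULT_TISSUES = ("leaf", "flower_bud", "pollen")

# stable per-stage RNG stream offsets
_CATALOG_STREAM = 11
_COUNTS_STREAM = 23
_GENO_STREAM = 37


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative scenario.

    Defaults describe a null scenario with respect to sex-chromosome
    processes: no retention bias (logistic slope 0 puts hemizygosity at
    50% among sex-linked genes), no pollenization, and a 1:1 X:Y
    expression share — while keeping a realistic amount of ordinary
    pollen-biased expression shared by both species.
    """

    n_genes: int = 2000
    frac_sex_linked: float = 0.15
    tissues: tuple = DEFAULT_TISSUES
    n_replicates_per_tissue: int = 3
    nb_dispersion: float = 0.1
    mean_log_expression: float = 5.0  # log2 scale
    sd_log_expression: float = 2.0
    frac_pollen_biased: float = 0.1
    pollen_bias_lfc: float = 2.0
    frac_leaf_biased: float = 0.1  # genes depleted in pollen by pollen_bias_lfc
    retention_logistic_intercept: float = 0.0
    retention_logistic_slope: float = 0.0
    frac_pollenized: float = 0.0
    pollenization_lfc: float = 1.0
    y_expression_share: float = 0.5
    allelic_log2_sd: float = 0.0  # per-XY-gene log2 jitter of the Y:X ratio
    n_males: int = 10
    n_females: int = 10
    sites_per_gene: int = 3
    frac_xpoly_decoy: float = 0.25
    genotyping_error: float = 0.005
    site_depth_frac: float = 0.1
    library_size: float = 20_000_000.0  # typical bulk Illumina RNA-seq depth
    seed: int = 0

    def __post_init__(self):
        for name in (
            "frac_sex_linked",
            "frac_pollen_biased",
            "frac_leaf_biased",
            "frac_pollenized",
            "frac_xpoly_decoy",
            "genotyping_error",
            "y_expression_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.allelic_log2_sd < 0:
            raise ValueError("allelic_log2_sd must be >= 0")
        for name in ("n_genes", "n_replicates_per_tissue", "n_males", "n_females"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sites_per_gene < 0:
            raise ValueError("sites_per_gene must be >= 0")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")
        if not 0.0 <= self.site_depth_frac <= 1.0:
            raise ValueError("site_depth_frac must be in [0, 1]")
        if len(self.tissues) == 0:
            raise ValueError("need at least one tissue")
        if self.frac_xpoly_decoy >= 1.0:
            raise ValueError("frac_xpoly_decoy must be < 1")

    # -- flat key=value config file round-trip -------------------------------
    def to_file(self, path):
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "tissues":
                kwargs[key] = tuple(x.strip() for x in val.split(",") if x.strip())
            elif key in ("n_genes", "n_replicates_per_tissue", "n_males",
                         "n_females", "sites_per_gene", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


def null_scenario(**overrides) -> SimConfig:
    """Null with respect to sex-chromosome processes (defaults)."""
    return SimConfig(**overrides)


def biased_retention_scenario(slope: float = -2.0, **overrides) -> SimConfig:
    """Pollen-expressed genes are preferentially retained on the Y."""
    return SimConfig(retention_logistic_slope=slope, **overrides)


def pollenization_scenario(
    frac: float = 0.3,
    lfc: float = 1.0,
    allelic_log2_sd: float = 0.4,
    **overrides,
) -> SimConfig:
    """A fraction of XY genes upregulates the Y allele in pollen.

    This scenario also carries tissue-independent X-Y expression
    divergence (``allelic_log2_sd``), as degenerating Y alleles show in
    every tissue; the leaf baseline of direction-biased genes that the
    tissue-vs-leaf contingency contrast needs comes from it.
    """
    return SimConfig(
        frac_pollenized=frac,
        pollenization_lfc=lfc,
        allelic_log2_sd=allelic_log2_sd,
        **overrides,
    )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def generate_catalog(config: SimConfig) -> pd.DataFrame:
    """Gene catalog for both species with a one-to-one ortholog map.

    Ancestral properties (baseline expression, length, pollen-bias status)
    are drawn once per ortholog pair and shared by the two species; the
    sex-linked gene sets of the two species are disjoint, so a gene that is
    sex-linked in one species is autosomal in the other.

    Returns a DataFrame with columns ``gene_id, species, length_bp,
    true_class, ortholog_id`` plus the simulation-truth columns
    ``base_log2_expr, pollen_biased, pollenized``.
    """
    if config.frac_sex_linked >= 0.5:
        raise ValueError(
            "frac_sex_linked >= 0.5 cannot keep sex-linked sets disjoint "
            "across the two species"
        )
    rng = _rng(config, _CATALOG_STREAM)
    n = config.n_genes

    ortholog_id = np.array([f"OG{i:06d}" for i in range(n)])
    length_bp = np.maximum(
        200, rng.lognormal(mean=np.log(1500), sigma=0.4, size=n)
    ).astype(np.int64)
    base = rng.normal(config.mean_log_expression, config.sd_log_expression, size=n)
    pollen_biased = rng.random(n) < config.frac_pollen_biased
    # leaf-biased genes are drawn from the remainder so the two sets are
    # disjoint; both states are ancestral (shared by the ortholog pair)
    leaf_biased = ~pollen_biased & (
        rng.random(n) < min(1.0, config.frac_leaf_biased / max(1e-12, 1 - config.frac_pollen_biased))
    )

    n_linked = int(np.floor(n * config.frac_sex_linked))
    perm = rng.permutation(n)
    linked = {"A": perm[:n_linked], "B": perm[n_linked : 2 * n_linked]}

    frames = []
    for sp in SPECIES:
        true_class = np.full(n, "autosomal", dtype=object)
        idx = linked[sp]
        if idx.size:
            # hemizygosity probability: logistic in standardized pollen expression
            pollen_expr = base + config.pollen_bias_lfc * (
                pollen_biased.astype(float) - leaf_biased.astype(float)
            )
            z = pollen_expr[idx]
            sd = z.std()
            z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
            logit = config.retention_logistic_intercept + config.retention_logistic_slope * z
            p_hemi = 1.0 / (1.0 + np.exp(-logit))
            hemi = rng.random(idx.size) < p_hemi
            true_class[idx[hemi]] = "hemizygous"
            true_class[idx[~hemi]] = "XY"
        pollenized = np.zeros(n, dtype=bool)
        xy = true_class == "XY"
        pollenized[xy] = rng.random(int(xy.sum())) < config.frac_pollenized
        y_log2_offset = np.zeros(n)
        if config.allelic_log2_sd > 0:
            y_log2_offset[xy] = rng.normal(0.0, config.allelic_log2_sd, int(xy.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": [f"{sp}_g{i:05d}" for i in range(n)],
                    "species": sp,
                    "length_bp": length_bp,
                    "true_class": true_class,
                    "ortholog_id": ortholog_id,
                    "base_log2_expr": base,
                    "pollen_biased": pollen_biased,
                    "leaf_biased": leaf_biased,
                    "pollenized": pollenized,
                    "y_log2_offset": y_log2_offset,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _allele_weights(sub: pd.DataFrame, config: SimConfig):
    """Per-gene x tissue expression weights of the X and Y components.

    Returns (x_w, y_w), each an array of shape (n_genes, n_tissues) on a
    linear (2**log2) scale. Autosomal genes carry their whole weight in
    x_w; hemizygous genes express the full gene mean from X alone.
    """
    tissues = list(config.tissues)
    base = 2.0 ** sub["base_log2_expr"].to_numpy(dtype=float)
    w = np.tile(base[:, None], (1, len(tissues)))
    if "pollen" in tissues:
        j = tissues.index("pollen")
        biased = sub["pollen_biased"].to_numpy(dtype=bool)
        w[biased, j] *= 2.0**config.pollen_bias_lfc
        depleted = sub["leaf_biased"].to_numpy(dtype=bool)
        w[depleted, j] *= 2.0**-config.pollen_bias_lfc

    cls = sub["true_class"].to_numpy()
    is_xy = cls == "XY"
    share = config.y_expression_share
    x_w = w.copy()
    y_w = np.zeros_like(w)
    x_w[is_xy] = w[is_xy] * (1.0 - share)
    y_w[is_xy] = w[is_xy] * share
    offset = sub["y_log2_offset"].to_numpy(dtype=float)
    y_w[is_xy] *= (2.0 ** offset[is_xy])[:, None]
    if "pollen" in tissues:
        j = tissues.index("pollen")
        pz = sub["pollenized"].to_numpy(dtype=bool)
        y_w[pz, j] *= 2.0**config.pollenization_lfc
    return x_w, y_w


def _sample_table(config: SimConfig, species: str) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for r in range(1, config.n_replicates_per_tissue + 1):
            rows.append(
                {
                    "sample": f"{species}_{tissue}_{r}",
                    "species": species,
                    "tissue": tissue,
                    "individual": f"{species}_{tissue}_M{r}",
                    "sex": "M",
                }
            )
    return pd.DataFrame(rows)


def simulate_counts(catalog: pd.DataFrame, config: SimConfig):
    """Negative-binomial read counts for every gene and sample.

    Returns ``(counts, meta)``: counts is genes x samples (both species;
    a gene has nonzero counts only in its own species' samples), meta has
    one row per sample with species, tissue, individual and sex.
    Expected column sums equal ``library_size``.
    """
    rng = _rng(config, _COUNTS_STREAM)
    tissues = list(config.tissues)
    all_counts = {}
    metas = []
    for sp in SPECIES:
        sub = catalog[catalog["species"] == sp].reset_index(drop=True)
        x_w, y_w = _allele_weights(sub, config)
        tot = x_w + y_w
        meta = _sample_table(config, sp)
        metas.append(meta)
        block = np.zeros((len(sub), len(meta)), dtype=np.int64)
        r = 1.0 / config.nb_dispersion
        for s, row in meta.iterrows():
            j = tissues.index(row["tissue"])
            w = tot[:, j]
            total_w = w.sum()
            mu = config.library_size * w / total_w if total_w > 0 else np.zeros_like(w)
            p_nb = r / (r + mu)
            block[:, s] = rng.negative_binomial(r, p_nb)
        all_counts[sp] = pd.DataFrame(
            block, index=sub["gene_id"].to_numpy(), columns=meta["sample"].to_numpy()
        )
    counts = (
        pd.concat(all_counts.values(), axis=0)
        .reindex(columns=[s for m in metas for s in m["sample"]])
        .fillna(0)
        .astype(np.int64)
    )
    counts.index.name = "gene_id"
    meta = pd.concat(metas, ignore_index=True)
    return counts, meta


# ---------------------------------------------------------------------------
# genotypes and allelic counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one scenario produces, ready for the analysis stages."""

    config: SimConfig
    catalog: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame
    panels: Dict[str, GenotypePanel] = field(default_factory=dict)
    allelic: pd.DataFrame | None = None
    site_truth: pd.DataFrame | None = None


def simulate_genotypes_and_allelic_counts(catalog, counts, meta, config):
    """Sexed genotype panels and per-site allelic read counts.

    Sex-linked genes (XY and hemizygous alike) carry ``sites_per_gene``
    fixed X-Y differences: before genotyping error all females are
    hom_ref and all males het — for hemizygous genes the divergent Y copy
    is present in the genome but silenced, so it still segregates. XY
    genes additionally carry X-polymorphism decoy sites (the confounder
    the fixed-difference filter exists to remove), and autosomal genes
    carry ordinary polymorphic sites. Genotype calls are replaced by a
    uniform random code with probability ``genotyping_error``.

    Allelic read depth per site is Poisson(``site_depth_frac`` x the
    gene's count in that sample); the alt (Y) read count is binomial with
    the gene's Y expression share in that sample's tissue.

    Returns ``(panels, allelic, site_truth)`` where panels maps species to
    :class:`~haplosel.sexlinkage.GenotypePanel`, allelic is a long table
    (gene_id, site_pos, sample, ref_count, alt_count) and site_truth
    records each simulated site's true type.
    """
    if config.sites_per_gene == 0 and (catalog["true_class"] != "autosomal").any():
        raise ValueError("sites_per_gene = 0 leaves XY genes without ASE sites")
    rng = _rng(config, _GENO_STREAM)
    tissues = list(config.tissues)
    f = config.frac_xpoly_decoy
    n_decoy = int(round(config.sites_per_gene * f / (1.0 - f))) if f > 0 else 0

    panels: Dict[str, GenotypePanel] = {}
    allelic_frames = []
    truth_frames = []
    for sp in SPECIES:
        sub = catalog[catalog["species"] == sp].reset_index(drop=True)
        males = [f"{sp}_pM{i + 1}" for i in range(config.n_males)]
        females = [f"{sp}_pF{i + 1}" for i in range(config.n_females)]
        individuals = pd.DataFrame(
            {"individual": males + females, "sex": ["M"] * len(males) + ["F"] * len(females)}
        )
        nm, nf = len(males), len(females)

        cls = sub["true_class"].to_numpy()
        sex_linked = sub.loc[cls != "autosomal", "gene_id"].to_numpy()
        xy_genes = sub.loc[cls == "XY", "gene_id"].to_numpy()
        auto_genes = sub.loc[cls == "autosomal", "gene_id"].to_numpy()
        S = config.sites_per_gene

        idx_genes, idx_pos, types, blocks, freqs = [], [], [], [], []

        # fixed X-Y differences on all sex-linked genes
        if sex_linked.size and S:
            n_sites = sex_linked.size * S
            g = np.column_stack(
                [np.full((n_sites, nm), HET), np.full((n_sites, nf), HOM_REF)]
            ).astype(np.int8)
            idx_genes.append(np.repeat(sex_linked, S))
            idx_pos.append(np.tile(100 * (np.arange(S) + 1), sex_linked.size))
            types.append(np.full(n_sites, "fixed_xy"))
            freqs.append(np.full(n_sites, np.nan))
            blocks.append(g)

        # X-polymorphism decoys on XY genes (males are hemizygous for X,
        # so a diploid caller sees them as homozygous for one allele)
        if xy_genes.size and n_decoy:
            n_sites = xy_genes.size * n_decoy
            af = rng.uniform(0.05, 0.95, n_sites)  # alt-allele frequency on X
            gm = 2 * rng.binomial(1, af[:, None], (n_sites, nm))
            gf = rng.binomial(2, af[:, None], (n_sites, nf))
            g = np.column_stack([gm, gf]).astype(np.int8)
            idx_genes.append(np.repeat(xy_genes, n_decoy))
            idx_pos.append(np.tile(100 * (np.arange(n_decoy) + 1) + 50, xy_genes.size))
            types.append(np.full(n_sites, "x_poly"))
            freqs.append(af)
            blocks.append(g)

        # ordinary polymorphic sites on autosomal genes
        if auto_genes.size and S:
            n_sites = auto_genes.size * S
            af = rng.uniform(0.05, 0.95, n_sites)
            g = rng.binomial(2, af[:, None], (n_sites, nm + nf)).astype(np.int8)
            idx_genes.append(np.repeat(auto_genes, S))
            idx_pos.append(np.tile(100 * (np.arange(S) + 1), auto_genes.size))
            types.append(np.full(n_sites, "autosomal_poly"))
            freqs.append(af)
            blocks.append(g)

        gene_arr = np.concatenate(idx_genes) if idx_genes else np.array([], dtype=object)
        pos_arr = np.concatenate(idx_pos) if idx_pos else np.array([], dtype=int)
        type_arr = np.concatenate(types) if types else np.array([], dtype=object)
        freq_arr = np.concatenate(freqs) if freqs else np.array([], dtype=float)
        G = np.vstack(blocks) if blocks else np.empty((0, nm + nf), dtype=np.int8)

        # genotyping error: replace with a uniform draw from the three codes
        if config.genotyping_error > 0 and G.size:
            mask = rng.random(G.shape) < config.genotyping_error
            G[mask] = rng.integers(0, 3, int(mask.sum()), dtype=np.int8)

        genotypes = pd.DataFrame(
            G,
            index=pd.MultiIndex.from_arrays([gene_arr, pos_arr], names=["gene_id", "pos"]),
            columns=males + females,
        )
        panels[sp] = GenotypePanel(individuals=individuals, genotypes=genotypes)
        truth_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_arr,
                    "pos": pos_arr,
                    "species": sp,
                    "true_type": type_arr,
                    "alt_freq": freq_arr,
                }
            )
        )

        # ---- allelic expression counts on sex-linked gene sites ----------
        sl_mask = np.isin(gene_arr, sex_linked) | np.isin(gene_arr, xy_genes)
        if not sl_mask.any():
            continue
        site_genes = gene_arr[sl_mask]
        site_pos = pos_arr[sl_mask]
        site_type = type_arr[sl_mask]
        site_af = freq_arr[sl_mask]

        sp_meta = meta[meta["species"] == sp].reset_index(drop=True)
        sp_samples = sp_meta["sample"].to_numpy()
        cnt = counts.loc[sub["gene_id"], sp_samples].to_numpy(dtype=float)
        gene_row = {g: i for i, g in enumerate(sub["gene_id"])}
        rows = np.array([gene_row[g] for g in site_genes])

        x_w, y_w = _allele_weights(sub, config)
        with np.errstate(invalid="ignore"):
            y_frac = np.where(x_w + y_w > 0, y_w / (x_w + y_w), 0.0)
        t_idx = np.array([tissues.index(t) for t in sp_meta["tissue"]])

        lam = config.site_depth_frac * cnt[rows][:, :]  # (n_sites, n_samples)
        depth = rng.poisson(lam)
        yf = y_frac[rows][:, t_idx]
        alt = rng.binomial(depth, yf)
        # decoy sites: each expression sample is its own male, expressing
        # the single X allele it carries at that site
        decoy = site_type == "x_poly"
        if decoy.any():
            allele = rng.binomial(1, site_af[decoy][:, None], (int(decoy.sum()), len(sp_samples)))
            alt[decoy] = depth[decoy] * allele
        ref = depth - alt

        n_sites_sl = len(site_genes)
        long = pd.DataFrame(
            {
                "gene_id": np.repeat(site_genes, len(sp_samples)),
                "site_pos": np.repeat(site_pos, len(sp_samples)),
                "sample": np.tile(sp_samples, n_sites_sl),
                "ref_count": ref.ravel(),
                "alt_count": alt.ravel(),
            }
        )
        allelic_frames.append(long[(long["ref_count"] + long["alt_count"]) > 0])

    allelic = (
        pd.concat(allelic_frames, ignore_index=True)
        if allelic_frames
        else pd.DataFrame(columns=["gene_id", "site_pos", "sample", "ref_count", "alt_count"])
    )
    site_truth = pd.concat(truth_frames, ignore_index=True)
    return panels, allelic, site_truth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run all three generators and bundle the results."""
    catalog = generate_catalog(config)
    counts, meta = simulate_counts(catalog, config)
    panels, allelic, site_truth = simulate_genotypes_and_allelic_counts(
        catalog, counts, meta, config
    )
    return SimulatedDataset(
        config=config,
        catalog=catalog,
        counts=counts,
        meta=meta,
        panels=panels,
        allelic=allelic,
        site_truth=site_truth,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=int(seed))
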