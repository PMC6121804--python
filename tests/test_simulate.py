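"""The synthetic-data generator: determinism, degenerate limits, and
statistical structure of the generated catalogs, counts and genotypes."""

import numpy as np
import pandas as pd
import pytest

import haplosel as h
from haplosel import simulate
from haplosel.sexlinkage import HET, HOM_REF


class TestCatalog:
    def test_no_sex_linkage_when_fraction_zero(self):
        cfg = h.SimConfig(n_genes=300, frac_sex_linked=0.0, seed=1)
        cat = simulate.generate_catalog(cfg)
        assert (cat["true_class"] == "autosomal").all()

    def test_rejects_fraction_half_or_more(self):
        with pytest.raises(ValueError, match="disjoint"):
            simulate.generate_catalog(h.SimConfig(n_genes=100, frac_sex_linked=0.5))

    def test_deterministic_under_seed(self):
        cfg = h.SimConfig(n_genes=200, seed=42)
        a = simulate.generate_catalog(cfg)
        b = simulate.generate_catalog(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_sex_linked_sets_disjoint_across_species(self):
        cfg = h.SimConfig(n_genes=1000, frac_sex_linked=0.3, seed=5)
        cat = simulate.generate_catalog(cfg)
        linked = {
            sp: set(
                cat.loc[
                    (cat["species"] == sp) & (cat["true_class"] != "autosomal"),
                    "ortholog_id",
                ]
            )
            for sp in ("A", "B")
        }
        assert not linked["A"] & linked["B"]
        assert len(linked["A"]) == int(1000 * 0.3)

    def test_ortholog_map_is_bijection(self):
        cat = simulate.generate_catalog(h.SimConfig(n_genes=150, seed=2))
        for sp in ("A", "B"):
            ids = cat.loc[cat["species"] == sp, "ortholog_id"]
            assert ids.is_unique

    def test_flat_retention_gives_half_hemizygous(self):
        # slope 0, intercept 0: hemizygosity is a fair coin among sex-linked
        cfg = h.SimConfig(
            n_genes=2000,
            frac_sex_linked=0.4,
            retention_logistic_slope=0.0,
            retention_logistic_intercept=0.0,
            seed=7,
        )
        cat = simulate.generate_catalog(cfg)
        linked = cat[cat["true_class"] != "autosomal"]
        frac_hemi = (linked["true_class"] == "hemizygous").mean()
        n = len(linked)
        se = np.sqrt(0.25 / n)
        assert abs(frac_hemi - 0.5) < 4 * se

    def test_negative_slope_retains_pollen_expressed_genes(self):
        cfg = simulate.biased_retention_scenario(n_genes=3000, seed=3)
        cat = simulate.generate_catalog(cfg)
        linked = cat[(cat["species"] == "A") & (cat["true_class"] != "autosomal")]
        expr = linked["base_log2_expr"] + cfg.pollen_bias_lfc * linked["pollen_biased"]
        hemi = linked["true_class"] == "hemizygous"
        assert expr[hemi].mean() < expr[~hemi].mean()


class TestCounts:
    def test_null_pollen_leaf_ratio_centred(self):
        cfg = h.SimConfig(
            n_genes=5000, frac_pollen_biased=0.0, frac_leaf_biased=0.0,
            frac_sex_linked=0.0, seed=9
        )
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        m = meta[meta["species"] == "A"]
        pollen = counts[m.loc[m["tissue"] == "pollen", "sample"]].mean(axis=1)
        leaf = counts[m.loc[m["tissue"] == "leaf", "sample"]].mean(axis=1)
        genes = cat.loc[cat["species"] == "A", "gene_id"]
        lfc = np.log2((pollen[genes] + 0.5) / (leaf[genes] + 0.5))
        assert abs(lfc.mean()) < 0.05

    def test_pollen_bias_lfc_realized(self):
        cfg = h.SimConfig(
            n_genes=5000, frac_pollen_biased=0.2, pollen_bias_lfc=2.0,
            frac_leaf_biased=0.0, frac_sex_linked=0.0, seed=13,
        )
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        sub = cat[cat["species"] == "A"].set_index("gene_id")
        m = meta[meta["species"] == "A"]
        pollen = counts.loc[sub.index, m.loc[m["tissue"] == "pollen", "sample"]].mean(axis=1)
        leaf = counts.loc[sub.index, m.loc[m["tissue"] == "leaf", "sample"]].mean(axis=1)
        lfc = np.log2((pollen + 0.5) / (leaf + 0.5))
        biased = sub["pollen_biased"]
        # flagged genes ~4x the unflagged ratio, within NB sampling error
        # (the global library normalization shifts both groups equally)
        assert lfc[biased].mean() - lfc[~biased].mean() == pytest.approx(2.0, abs=0.1)

    def test_zero_library_size_gives_all_zero(self):
        cfg = h.SimConfig(n_genes=100, library_size=0.0, seed=1)
        cat = simulate.generate_catalog(cfg)
        counts, _ = simulate.simulate_counts(cat, cfg)
        assert (counts.to_numpy() == 0).all()

    def test_column_sums_near_library_size(self):
        cfg = h.SimConfig(n_genes=2000, seed=21)
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        for sp in ("A", "B"):
            cols = meta.loc[meta["species"] == sp, "sample"]
            sums = counts[cols].sum(axis=0)
            # a handful of very highly expressed genes dominate each library,
            # so NB noise moves column totals by a few percent
            assert np.allclose(sums, cfg.library_size, rtol=0.1)

    def test_nb_mean_variance_relationship(self):
        # across genes at fixed dispersion, var ~= mu + alpha * mu^2
        cfg = h.SimConfig(
            n_genes=6000, nb_dispersion=0.2, frac_sex_linked=0.0,
            frac_pollen_biased=0.0, frac_leaf_biased=0.0, n_replicates_per_tissue=10,
            tissues=("leaf",), seed=17,
        )
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        cols = meta.loc[meta["species"] == "A", "sample"]
        c = counts[cols].to_numpy(float)[: cfg.n_genes]
        mu = c.mean(axis=1)
        var = c.var(axis=1, ddof=1)
        keep = mu > 50
        alpha_hat = np.median((var[keep] - mu[keep]) / mu[keep] ** 2)
        assert alpha_hat == pytest.approx(0.2, abs=0.05)

    def test_deterministic_under_seed(self):
        cfg = h.SimConfig(n_genes=150, seed=4)
        cat = simulate.generate_catalog(cfg)
        c1, m1 = simulate.simulate_counts(cat, cfg)
        c2, m2 = simulate.simulate_counts(cat, cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)


@pytest.fixture(scope="module")
def dataset():
    cfg = h.SimConfig(n_genes=500, genotyping_error=0.0, seed=31)
    return h.simulate_dataset(cfg)


class TestGenotypesAndAllelic:

    def test_error_free_fixed_sites_follow_rule_exactly(self, dataset):
        truth = dataset.site_truth
        panel = dataset.panels["A"]
        fixed = truth[(truth["species"] == "A") & (truth["true_type"] == "fixed_xy")]
        males = panel.columns_by_sex("M")
        females = panel.columns_by_sex("F")
        sites = panel.genotypes.loc[list(zip(fixed["gene_id"], fixed["pos"]))]
        assert (sites[males].to_numpy() == HET).all()
        assert (sites[females].to_numpy() == HOM_REF).all()

    def test_hemizygous_genes_have_zero_alt_reads(self, dataset):
        hemi = dataset.catalog.loc[
            dataset.catalog["true_class"] == "hemizygous", "gene_id"
        ]
        sub = dataset.allelic[dataset.allelic["gene_id"].isin(set(hemi))]
        assert len(sub) > 0
        assert (sub["alt_count"] == 0).all()

    def test_balanced_xy_alt_fraction_half(self):
        # X:Y at 1:1 -> alt fraction 0.5 within 3 SE over ~1000 site-samples
        cfg = h.SimConfig(n_genes=800, frac_sex_linked=0.4, seed=37)
        ds = h.simulate_dataset(cfg)
        xy = set(ds.catalog.loc[ds.catalog["true_class"] == "XY", "gene_id"])
        fixed = ds.site_truth[ds.site_truth["true_type"] == "fixed_xy"]
        keys = set(zip(fixed["gene_id"], fixed["pos"]))
        in_keys = np.array(
            [k in keys for k in zip(ds.allelic["gene_id"], ds.allelic["site_pos"])]
        )
        sub = ds.allelic[ds.allelic["gene_id"].isin(xy).to_numpy() & in_keys]
        # leaf tissue only: no pollenization anywhere in this config anyway
        total = (sub["ref_count"] + sub["alt_count"]).sum()
        frac = sub["alt_count"].sum() / total
        se = np.sqrt(0.25 / total)
        assert abs(frac - 0.5) < 3 * se + 1e-9

    def test_rejects_zero_sites_with_xy_genes(self):
        cfg = h.SimConfig(n_genes=100, sites_per_gene=0, seed=1)
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        with pytest.raises(ValueError, match="sites_per_gene"):
            simulate.simulate_genotypes_and_allelic_counts(cat, counts, meta, cfg)

    def test_deterministic_under_seed(self):
        cfg = h.SimConfig(n_genes=120, seed=8)
        cat = simulate.generate_catalog(cfg)
        counts, meta = simulate.simulate_counts(cat, cfg)
        p1, a1, t1 = simulate.simulate_genotypes_and_allelic_counts(cat, counts, meta, cfg)
        p2, a2, t2 = simulate.simulate_genotypes_and_allelic_counts(cat, counts, meta, cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)
        for sp in p1:
            pd.testing.assert_frame_equal(p1[sp].genotypes, p2[sp].genotypes)


class TestConfig:
    def test_roundtrip_through_file(self, tmp_path):
        cfg = h.SimConfig(n_genes=123, frac_sex_linked=0.2, seed=99)
        path = tmp_path / "config.txt"
        cfg.to_file(path)
        assert h.SimConfig.from_file(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_sex_linked": -0.1},
            {"nb_dispersion": 0.0},
            {"n_genes": 0},
            {"genotyping_error": 1.5},
            {"library_size": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            h.SimConfig(**kwargs)
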