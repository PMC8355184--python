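"""Generator contracts: determinism, planted structure, truth-table fidelity."""

import numpy as np
import pandas as pd
import pytest

from locop import pleio, preprocess, simdata
from locop.simdata import SimConfig


def small_cfg(**kw):
    base = dict(
        n_individuals=100, n_genes=50, n_chromosomes=2, mean_tss_spacing=50_000, seed=3
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"mean_tss_spacing": 0},
            {"mean_tss_spacing": -5},
            {"n_genes": 1},
            {"n_chromosomes": 0},
            {"block_spec": [(60, 0.5)]},  # exceeds n_genes
            {"block_spec": [(2, 1.0)]},  # loading out of [0,1)
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestGenome:
    def test_tss_strictly_increasing_per_chromosome(self):
        cat = simdata.simulate_genome(small_cfg(n_genes=200))
        for _, grp in cat.groupby("chrom"):
            assert (np.diff(grp["tss"].to_numpy()) > 0).all()
        assert set(cat["biotype"]) <= {"protein_coding", "lincRNA"}
        assert set(cat["strand"]) <= {"+", "-"}

    def test_dense_single_chromosome_all_pairs_cis(self):
        from locop.copcall import enumerate_cis_pairs

        # 10 genes at ~50 kb spacing span well under 1 Mb on one chromosome
        cfg = small_cfg(n_genes=10, n_chromosomes=1, mean_tss_spacing=50_000, seed=9)
        cat = simdata.simulate_genome(cfg)
        if cat["tss"].max() - cat["tss"].min() < 1_000_000:
            assert len(enumerate_cis_pairs(cat)) == 45

    def test_two_genes_on_different_chromosomes_not_cis(self):
        from locop.copcall import enumerate_cis_pairs

        cfg = small_cfg(n_genes=2, n_chromosomes=2)
        cat = simdata.simulate_genome(cfg)
        assert len(enumerate_cis_pairs(cat)) == 0

    def test_determinism_and_seed_sensitivity(self):
        a = simdata.simulate_genome(small_cfg())
        b = simdata.simulate_genome(small_cfg())
        c = simdata.simulate_genome(small_cfg(seed=4))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestExpression:
    def test_block_correlation_matches_squared_loading(self):
        # shared-factor model: corr(a*f + s*e1, a*f + s*e2) = a^2
        cfg = small_cfg(
            n_individuals=500, n_genes=100, block_spec=[(2, 0.9)] * 20, seed=11
        )
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        idx = expr.gene_index()
        rs = [
            np.corrcoef(expr.values[idx[a]], expr.values[idx[b]])[0, 1]
            for a, b in zip(truth["gene_a"], truth["gene_b"])
        ]
        assert abs(np.mean(rs) - 0.81) < 0.05

    def test_zero_loading_gives_null_correlations(self):
        cfg = small_cfg(n_individuals=500, n_genes=60, block_spec=[(2, 0.0)] * 10)
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        idx = expr.gene_index()
        rs = [
            np.corrcoef(expr.values[idx[a]], expr.values[idx[b]])[0, 1]
            for a, b in zip(truth["gene_a"], truth["gene_b"])
        ]
        assert abs(np.mean(rs)) < 0.1  # ~N(0, 1/sqrt(500)) each

    def test_no_confounders_means_no_confounder_signal(self):
        cfg = small_cfg(confounder_count=0, confounder_strength=0.0)
        cat = simdata.simulate_genome(cfg)
        expr, _, conf = simdata.simulate_expression(cat, cfg)
        assert conf.shape[1] == 0
        assert np.isfinite(expr.values).all()

    def test_confounders_removed_by_residualization(self):
        cfg = small_cfg(
            n_individuals=300, confounder_count=2, confounder_strength=1.0
        )
        cat = simdata.simulate_genome(cfg)
        expr, _, conf = simdata.simulate_expression(cat, cfg)
        expr, _ = preprocess.filter_genes(expr, cat, preprocess.FilterRules())
        res = preprocess.residualize(expr, conf)
        # residuals orthogonal to each confounder
        for k in range(conf.shape[1]):
            dots = res.values @ conf.iloc[:, k].to_numpy()
            assert np.allclose(dots, 0.0, atol=1e-8)

    def test_block_bigger_than_chromosome_errors(self):
        cfg = small_cfg(n_genes=10, n_chromosomes=2, block_spec=[(9, 0.5)])
        cat = simdata.simulate_genome(cfg)
        with pytest.raises(ValueError):
            simdata.simulate_expression(cat, cfg)


class TestGenotypes:
    def test_dosages_in_012_and_maf_close_to_nominal(self):
        cfg = small_cfg(n_individuals=200, variants_per_gene=5)
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        geno, _, _ = simdata.simulate_genotypes_and_eqtls(cat, expr, truth, cfg)
        assert set(np.unique(geno.dosages)) <= {0, 1, 2}
        emp = geno.empirical_maf()
        nominal = geno.variants["maf"].to_numpy()
        assert np.all(np.abs(emp - np.minimum(nominal, 1 - nominal)) <= 0.1)

    def test_zero_beta_leaves_expression_unchanged(self):
        cfg = small_cfg(eqtl_effect=0.0, egene_fraction=0.5, variants_per_gene=3)
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        _, _, expr2 = simdata.simulate_genotypes_and_eqtls(cat, expr, truth, cfg)
        np.testing.assert_array_equal(expr.values, expr2.values)

    def test_shared_fraction_one_marks_every_pair_eqtl_shared(self):
        cfg = small_cfg(
            block_spec=[(2, 0.5)] * 10, shared_fraction=1.0, variants_per_gene=5
        )
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        _, eqtl_truth, _ = simdata.simulate_genotypes_and_eqtls(cat, expr, truth, cfg)
        assert eqtl_truth["shared"].all()
        # both members of each pair carry the shared variant
        per_pair = eqtl_truth.groupby("pair_id")["gene_id"].nunique()
        assert (per_pair == 2).all()

    def test_truth_tables_reference_existing_ids(self, planted_dataset):
        ds = planted_dataset
        genes = set(ds.catalog["gene_id"])
        variants = set(ds.genotypes.variants["variant_id"])
        assert set(ds.truth_pairs["gene_a"]) | set(ds.truth_pairs["gene_b"]) <= genes
        assert set(ds.eqtl_truth["gene_id"]) <= genes
        assert set(ds.eqtl_truth["variant_id"]) <= variants

    def test_ols_recovers_planted_beta(self):
        # beta 0.5, MAF 0.3, n=500: OLS on dosage is consistent
        cfg = small_cfg(
            n_individuals=500,
            n_genes=20,
            block_spec=[],
            egene_fraction=1.0,
            eqtl_effect=0.5,
            maf_range=(0.3, 0.3),
            variants_per_gene=1,
        )
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        geno, eqtl_truth, expr = simdata.simulate_genotypes_and_eqtls(
            cat, expr, truth, cfg
        )
        gi = expr.gene_index()
        vi = geno.variant_index()
        betas = []
        for rec in eqtl_truth.itertuples(index=False):
            y = expr.values[gi[rec.gene_id]]
            d = geno.dosages[vi[rec.variant_id]].astype(float)
            betas.append(np.polyfit(d, y, 1)[0])
        assert abs(np.mean(betas) - 0.5) < 0.1


class TestTracks:
    def _tracks(self, depletion, seed=3):
        cfg = small_cfg(
            n_genes=200,
            n_individuals=50,
            block_spec=[(2, 0.5)] * 50,
            track_depletion=depletion,
            seed=seed,
        )
        cat = simdata.simulate_genome(cfg)
        _, truth, _ = simdata.simulate_expression(cat, cfg)
        tracks, links, hic = simdata.simulate_tracks(cat, truth, cfg)
        return cat, truth, tracks, links, hic

    @staticmethod
    def _between_counts(cat, pairs, track):
        from locop.features import IntervalTrack

        it = IntervalTrack("t", track)
        tss = dict(zip(cat["gene_id"], cat["tss"]))
        chrom = dict(zip(cat["gene_id"], cat["chrom"]))
        out = []
        for a, b in pairs:
            lo, hi = sorted((tss[a], tss[b]))
            out.append(it.count_overlapping(chrom[a], lo, hi))
        return np.array(out)

    def test_ctcf_depletion_halves_between_pair_counts(self):
        cat, truth, tracks, _, _ = self._tracks({"ctcf_sites": 0.5})
        true_pairs = list(zip(truth["gene_a"], truth["gene_b"]))
        depleted = self._between_counts(cat, true_pairs, tracks["ctcf_sites"])
        # Poisson thinning: expected count ratio equals the survival factor
        cat2, truth2, tracks2, _, _ = self._tracks({})
        neutral = self._between_counts(
            cat2, list(zip(truth2["gene_a"], truth2["gene_b"])), tracks2["ctcf_sites"]
        )
        assert depleted.mean() < neutral.mean()
        assert abs(depleted.mean() / max(neutral.mean(), 1e-9) - 0.5) < 0.25

    def test_no_depletion_is_neutral(self):
        cat, truth, tracks, _, _ = self._tracks({"ctcf_sites": 1.0})
        true_pairs = list(zip(truth["gene_a"], truth["gene_b"]))
        counts = self._between_counts(cat, true_pairs, tracks["ctcf_sites"])
        # neutral: counts scale with inter-TSS span at the configured density
        tss = dict(zip(cat["gene_id"], cat["tss"]))
        spans = np.array([abs(tss[a] - tss[b]) for a, b in true_pairs])
        expected = 20.0 * spans.sum() / 1e6
        assert abs(counts.sum() - expected) / expected < 0.35

    def test_hic_power_law_decay(self):
        cat, truth, tracks, links, hic = self._tracks({})
        # contacts halve (in expectation) when bin distance doubles at decay -1
        hic = hic.assign(dist=(hic["bin2_start"] - hic["bin1_start"]))
        d1 = hic.loc[(hic["dist"] >= 20_000) & (hic["dist"] < 40_000), "count"]
        d2 = hic.loc[(hic["dist"] >= 40_000) & (hic["dist"] < 80_000), "count"]
        assert d1.mean() > d2.mean()
        assert 1.4 < d1.mean() / d2.mean() < 2.9


class TestGwas:
    def test_uniform_null_lambda_one(self):
        cfg = small_cfg(n_genes=500, n_individuals=10, variants_per_gene=20, gwas_traits=2)
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        geno, eqtl_truth, _ = simdata.simulate_genotypes_and_eqtls(cat, expr, truth, cfg)
        gwas = simdata.simulate_gwas(geno.variants, eqtl_truth.iloc[:0], cfg)
        p = gwas.loc[gwas["trait_id"] == "T00", "pval"].to_numpy()
        assert len(p) == 10_000
        lam, _ = pleio.genomic_inflation(p)
        assert abs(lam - 1.0) < 0.05
        # null tail: essentially no genome-wide-significant hits
        assert (p < 5e-8).mean() < 1e-3

    def test_designated_hits_counted_per_trait(self):
        cfg = small_cfg(
            n_genes=40,
            block_spec=[(2, 0.5)] * 10,
            shared_fraction=1.0,
            gwas_traits=6,
            gwas_shared_hit_rate=1.0,
            gwas_hits_per_variant=3,
            variants_per_gene=3,
        )
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        geno, eqtl_truth, _ = simdata.simulate_genotypes_and_eqtls(cat, expr, truth, cfg)
        gwas = simdata.simulate_gwas(geno.variants, eqtl_truth, cfg)
        shared_vars = eqtl_truth.loc[eqtl_truth["shared"], "variant_id"].unique()
        counts, missing = pleio.trait_association_counts(gwas, list(shared_vars))
        assert not missing
        assert (counts >= 1).all()
        assert 2.0 < counts.mean() < 4.5  # mean designated hits per carrier ~3


class TestDeterminism:
    def test_full_dataset_reproducible(self):
        cfg = small_cfg(
            block_spec=[(2, 0.8)] * 5,
            egene_fraction=0.3,
            gwas_shared_hit_rate=0.5,
            variants_per_gene=3,
        )
        d1 = simdata.simulate_dataset(cfg)
        d2 = simdata.simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.expression.values, d2.expression.values)
        np.testing.assert_array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
        pd.testing.assert_frame_equal(d1.gwas, d2.gwas)
        pd.testing.assert_frame_equal(d1.truth_pairs, d2.truth_pairs)
        pd.testing.assert_frame_equal(d1.hic, d2.hic)
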