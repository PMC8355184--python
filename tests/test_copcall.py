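"""Discovery statistics: cis enumeration, permutation nulls, BH calling,
pair filters, components and tissue sharing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from locop import copcall, preprocess
from locop._seeds import derive_rng
from locop.copcall import (
    DiscoveryResult,
    apply_pair_filters,
    build_components,
    call_cops,
    enumerate_cis_pairs,
    gene_null,
    tissue_sharing,
)
from tests.conftest import toy_catalog


def int_expr(values):
    expr = preprocess.ExpressionMatrix(
        genes=[f"G{i}" for i in range(values.shape[0])],
        samples=[f"S{j}" for j in range(values.shape[1])],
        values=np.asarray(values, dtype=float),
        state="filtered",
    )
    return preprocess.inverse_normal_transform(expr)


class TestEnumerateCisPairs:
    def test_distance_recorded(self):
        pairs = enumerate_cis_pairs(toy_catalog([100_000, 600_000]))
        assert len(pairs) == 1
        assert pairs.iloc[0]["tss_distance"] == 500_000

    def test_window_boundary_strict(self):
        pairs = enumerate_cis_pairs(toy_catalog([0, 1_000_000]))
        assert pairs.empty
        pairs = enumerate_cis_pairs(toy_catalog([0, 999_999]))
        assert len(pairs) == 1

    def test_cross_chromosome_excluded(self):
        pairs = enumerate_cis_pairs(toy_catalog([0, 1000], chroms=["chr1", "chr2"]))
        assert pairs.empty

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        tss=st.lists(
            st.integers(min_value=0, max_value=3_000_000), min_size=2, max_size=12, unique=True
        ),
        window=st.integers(min_value=1, max_value=2_000_000),
    )
    def test_matches_quadratic_oracle(self, tss, window):
        cat = toy_catalog(sorted(tss))
        pairs = enumerate_cis_pairs(cat, window=window)
        expected = {
            tuple(sorted((f"G{i}", f"G{j}")))
            for i in range(len(tss))
            for j in range(i + 1, len(tss))
            if abs(sorted(tss)[i] - sorted(tss)[j]) < window
        }
        got = {tuple(sorted(k)) for k in zip(pairs["gene_a"], pairs["gene_b"])}
        assert got == expected


def brute_force_gene_null(expr, gene, cis_set, R, seed, statistic="abs"):
    """Independent re-implementation: per-permutation corrcoef loop."""
    idx = expr.gene_index()
    x = expr.values[idx[gene]]
    cis = [expr.values[idx[h]] for h in cis_set]
    stat = abs if statistic == "abs" else float
    obs = [np.corrcoef(x, h)[0, 1] for h in cis]
    rng = derive_rng(seed, "copcall", gene)
    null_max = []
    for _ in range(R):
        perm = rng.permutation(len(x))
        null_max.append(max(stat(np.corrcoef(x[perm], h)[0, 1]) for h in cis))
    null_max = np.asarray(null_max)
    adj = [
        (1 + np.sum(null_max >= stat(r))) / (R + 1)
        for r in obs
    ]
    return null_max, np.asarray(obs), np.asarray(adj)


class TestGeneNull:
    def test_matches_brute_force_permutation_for_permutation(self):
        rng = np.random.default_rng(21)
        expr = int_expr(rng.normal(size=(12, 40)))
        cis = [f"G{i}" for i in range(1, 12)]
        record, frame = gene_null(expr, "G0", cis, R=50, seed=17)
        nm, obs, adj = brute_force_gene_null(expr, "G0", cis, R=50, seed=17)
        np.testing.assert_allclose(record.null_maxima, nm, atol=1e-12)
        np.testing.assert_allclose(frame["obs_r"].to_numpy(), obs, atol=1e-12)
        np.testing.assert_allclose(frame["adj_p"].to_numpy(), adj, atol=0)

    def test_extreme_observation_floor(self):
        # planted near-perfect correlation beats all 100 null maxima
        rng = np.random.default_rng(22)
        base = rng.normal(size=60)
        vals = np.vstack([base, base + 0.05 * rng.normal(size=60), rng.normal(size=60)])
        expr = int_expr(vals)
        record, frame = gene_null(expr, "G0", ["G1", "G2"], R=100, seed=3)
        best = frame.loc[frame["obs_r"].abs().idxmax(), "adj_p"]
        assert best == pytest.approx(1 / 101)
        assert record.gene_adj_p == pytest.approx(1 / 101)

    def test_weak_observation_p_one(self):
        # observed r ~ 0 never beats the null maxima over many cis genes
        rng = np.random.default_rng(23)
        expr = int_expr(rng.normal(size=(21, 30)))
        _, frame = gene_null(expr, "G0", [f"G{i}" for i in range(1, 21)], R=60, seed=5)
        assert frame["adj_p"].max() == 1.0

    def test_requires_positive_r_and_nonempty_cis(self):
        expr = int_expr(np.random.default_rng(24).normal(size=(2, 10)))
        with pytest.raises(ValueError):
            gene_null(expr, "G0", ["G1"], R=0, seed=0)
        with pytest.raises(ValueError):
            gene_null(expr, "G0", [], R=10, seed=0)

    def test_null_gene_adjusted_p_uniform(self, null_discovery):
        """On fully null data the gene-level adjusted p-values are uniform."""
        pvals = np.array([rec.gene_adj_p for rec in null_discovery.nulls.values()])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCallCops:
    @staticmethod
    def _pairs(rows):
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "chrom", "tss_distance", "pearson_r", "adj_p_a", "adj_p_b"]
        )

    def test_artifact_pairs_removed_and_logged(self):
        pairs = self._pairs(
            [
                ("A", "B", "chr1", 100, 0.995, 0.001, 0.001),
                ("C", "D", "chr1", 100, 0.5, 0.001, 0.001),
            ]
        )
        res = call_cops(pairs, {}, fdr=0.5)
        assert res.pairs.loc[0, "filtered_reason"] == "artifact"
        assert not res.pairs.loc[0, "is_cop"]
        assert res.pairs.loc[1, "is_cop"]

    def test_both_sides_must_pass(self):
        pairs = self._pairs(
            [
                ("A", "B", "chr1", 100, 0.5, 0.001, 0.6),
                ("C", "D", "chr1", 100, 0.5, 0.002, 0.002),
            ]
        )
        res = call_cops(pairs, {}, fdr=0.05)
        cops = res.cops()
        assert len(cops) == 1 and cops.iloc[0]["gene_a"] == "C"

    def test_no_gene_passing_gives_nan_threshold(self):
        pairs = self._pairs([("A", "B", "chr1", 100, 0.1, 0.9, 0.8)])
        res = call_cops(pairs, {}, fdr=0.01)
        assert np.isnan(res.threshold)
        assert not res.pairs["is_cop"].any()

    def test_fdr_monotonicity(self, planted_discovery):
        """Raising the FDR level never removes a called pair."""
        strict = planted_discovery
        relaxed = call_cops(
            strict.pairs.drop(columns=["is_cop", "filtered_reason"]),
            strict.nulls,
            fdr=0.05,
        )
        strict_keys = set(map(tuple, strict.cops()[["gene_a", "gene_b"]].to_numpy()))
        relaxed_keys = set(map(tuple, relaxed.cops()[["gene_a", "gene_b"]].to_numpy()))
        assert strict_keys <= relaxed_keys

    def test_planted_blocks_recovered(self, planted_dataset, planted_discovery):
        """>=90% of planted high-loading pairs are called at FDR 1%."""
        truth = {
            tuple(sorted(t))
            for t in zip(
                planted_dataset.truth_pairs["gene_a"],
                planted_dataset.truth_pairs["gene_b"],
            )
        }
        called = {
            tuple(sorted(t))
            for t in zip(
                planted_discovery.cops()["gene_a"], planted_discovery.cops()["gene_b"]
            )
        }
        assert len(truth & called) / len(truth) >= 0.9

    def test_fully_null_declares_almost_nothing(self, null_discovery):
        cop_genes = set(null_discovery.cops()["gene_a"]) | set(
            null_discovery.cops()["gene_b"]
        )
        n_tested = len(null_discovery.nulls)
        assert len(cop_genes) / n_tested <= 0.01


class TestPairSymmetryAndOrderInvariance:
    def test_correlation_symmetric_and_canonical(self, planted_discovery):
        pairs = planted_discovery.pairs
        assert (pairs["gene_a"] < pairs["gene_b"]).all()
        assert not pairs.duplicated(subset=["gene_a", "gene_b"]).any()

    def test_gene_order_does_not_change_discovery(self):
        rng = np.random.default_rng(30)
        vals = rng.normal(size=(10, 50))
        cat = toy_catalog(list(range(0, 500_000, 50_000)))
        expr = int_expr(vals)
        res1 = copcall.discover(expr, cat, R=30, seed=9)
        # reverse gene order in both expression and catalog
        rev = preprocess.ExpressionMatrix(
            expr.genes[::-1].copy(), expr.samples, expr.values[::-1].copy(), state="int"
        )
        res2 = copcall.discover(rev, cat.iloc[::-1], R=30, seed=9)
        p1 = res1.pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        p2 = res2.pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(p1, p2)


class TestApplyPairFilters:
    @staticmethod
    def _result():
        pairs = pd.DataFrame(
            {
                "gene_a": ["A", "C", "E"],
                "gene_b": ["B", "D", "F"],
                "chrom": ["chr1"] * 3,
                "tss_distance": [100, 200, 300],
                "pearson_r": [0.5, -0.3, 0.4],
                "adj_p_a": [0.001] * 3,
                "adj_p_b": [0.001] * 3,
                "is_cop": [True, True, True],
                "filtered_reason": [None, None, None],
            }
        )
        return DiscoveryResult(pairs=pairs, nulls={}, threshold=0.01, fdr=0.01)

    def test_negative_and_paralog_cops_removed(self):
        paralogs = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"]})
        out = apply_pair_filters(self._result(), paralogs)
        reasons = dict(
            zip(out.pairs["gene_a"], out.pairs["filtered_reason"])
        )
        assert reasons["A"] == "paralog"
        assert reasons["C"] == "negative"
        assert out.cops()["gene_a"].tolist() == ["E"]

    def test_identity_with_no_filters(self):
        out = apply_pair_filters(self._result(), None, keep_sign="any")
        assert out.pairs["is_cop"].all()


class TestComponents:
    @staticmethod
    def _result_from_edges(edges):
        pairs = pd.DataFrame(
            {
                "gene_a": [min(e) for e in edges],
                "gene_b": [max(e) for e in edges],
                "chrom": "chr1",
                "tss_distance": 1,
                "pearson_r": 0.5,
                "adj_p_a": 0.001,
                "adj_p_b": 0.001,
                "is_cop": True,
                "filtered_reason": None,
            }
        )
        return DiscoveryResult(pairs=pairs, nulls={}, threshold=0.01, fdr=0.01)

    def test_chain_forms_single_component(self):
        table, member = build_components(self._result_from_edges([("A", "B"), ("B", "C")]))
        assert len(table) == 1
        assert table.iloc[0]["n_genes"] == 3 and table.iloc[0]["n_edges"] == 2

    def test_disjoint_pairs_stay_separate(self):
        table, member = build_components(self._result_from_edges([("A", "B"), ("C", "D")]))
        assert len(table) == 2
        assert set(table["n_genes"]) == {2}
        assert member["A"] != member["C"]

    def test_planted_block_sizes_recovered(self):
        from locop import simdata

        cfg = simdata.SimConfig(
            n_individuals=300,
            n_genes=40,
            n_chromosomes=1,
            mean_tss_spacing=50_000,
            block_spec=[(5, 0.9)] + [(3, 0.9)] + [(2, 0.9)] * 13,
            seed=33,
        )
        cat = simdata.simulate_genome(cfg)
        expr, truth, _ = simdata.simulate_expression(cat, cfg)
        expr, _ = preprocess.filter_genes(expr, cat, preprocess.FilterRules())
        expr = preprocess.inverse_normal_transform(expr)
        res = copcall.discover(expr, cat, R=200, fdr=0.01, seed=2)
        table, _ = build_components(res)
        assert {5, 3} <= set(table["n_genes"])


class TestTissueSharing:
    @staticmethod
    def _result(cop_keys):
        pairs = pd.DataFrame(
            {
                "gene_a": [k.split("|")[0] for k in cop_keys],
                "gene_b": [k.split("|")[1] for k in cop_keys],
                "chrom": "chr1",
                "tss_distance": 1,
                "pearson_r": 0.5,
                "adj_p_a": 0.001,
                "adj_p_b": 0.001,
                "is_cop": True,
                "filtered_reason": None,
            }
        )
        return DiscoveryResult(pairs=pairs, nulls={}, threshold=0.01, fdr=0.01)

    def test_categories_follow_prevalence_ratio(self):
        tissues = [f"t{i}" for i in range(10)]
        # P1: COP in 1/10 -> unique; P2: 6/10 -> conserved; P3: 1 tissue only
        results = {}
        for i, t in enumerate(tissues):
            keys = []
            if i == 0:
                keys.append("A|B")
            if i < 6:
                keys.append("C|D")
            if i < 1:
                keys.append("E|F")
            results[t] = self._result(keys)
        presence = pd.DataFrame(
            True, index=["A|B", "C|D", "E|F"], columns=tissues
        )
        presence.loc["E|F", tissues[3:]] = False  # co-present in only 3 < 5 tissues
        mat, cats = tissue_sharing(results, presence)
        cat = dict(zip(cats["pair"], cats["category"]))
        assert cat["A|B"] == "unique"
        assert cat["C|D"] == "conserved"
        assert "E|F" not in cat  # excluded: co-present in < 5 tissues

    def test_specific_category_at_ten_percent(self):
        tissues = [f"t{i}" for i in range(20)]
        results = {
            t: self._result(["A|B"] if i < 2 else []) for i, t in enumerate(tissues)
        }
        presence = pd.DataFrame(True, index=["A|B"], columns=tissues)
        _, cats = tissue_sharing(results, presence)
        assert cats.iloc[0]["category"] == "specific"  # 2/20 = 10% <= 15%

    def test_sharing_matrix_is_directional(self):
        results = {
            "t0": self._result(["A|B", "C|D"]),
            "t1": self._result(["A|B"]),
        }
        presence = pd.DataFrame(True, index=["A|B", "C|D"], columns=["t0", "t1"])
        mat, _ = tissue_sharing(results, presence, min_tissues=1)
        assert mat.loc["t0", "t1"] == 50.0  # 1 of t0's 2 COPs replicates in t1
        assert mat.loc["t1", "t0"] == 100.0
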