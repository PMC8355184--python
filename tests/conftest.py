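import numpy as np
import pandas as pd
import pytest

from locop import copcall, preprocess, simdata


def toy_catalog(tss_list, chroms=None, strands=None, biotypes=None):
    """Small hand-built gene catalog for unit tests."""
    n = len(tss_list)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "chrom": chroms or ["chr1"] * n,
            "tss": tss_list,
            "strand": strands or ["+"] * n,
            "biotype": biotypes or ["protein_coding"] * n,
        }
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Dataset with 100 planted pairs, eQTLs, depleted tracks and GWAS hits.

    Shared across tests that only read from it.
    """
    cfg = simdata.SimConfig(
        n_individuals=300,
        n_genes=300,
        n_chromosomes=2,
        mean_tss_spacing=100_000,
        block_spec=[(2, 0.9)] * 100,
        confounder_count=0,
        egene_fraction=0.5,
        shared_fraction=0.5,
        variants_per_gene=10,
        track_depletion={"ctcf_sites": 0.5, "tf_motifs": 0.5},
        enhancer_depletion=0.5,
        go_rate_true=0.5,
        paralog_rate_true=0.05,
        gwas_traits=5,
        gwas_shared_hit_rate=0.3,
        gwas_other_hit_rate=0.15,
        gwas_shared_inflation=1.6,
        gwas_other_inflation=1.3,
        seed=7,
    )
    return simdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_int_expression(planted_dataset):
    expr, _ = preprocess.filter_genes(
        planted_dataset.expression, planted_dataset.catalog, preprocess.FilterRules()
    )
    return preprocess.inverse_normal_transform(expr)


@pytest.fixture(scope="session")
def planted_discovery(planted_dataset, planted_int_expression):
    return copcall.discover(
        planted_int_expression, planted_dataset.catalog, R=200, fdr=0.01, seed=1
    )


@pytest.fixture(scope="session")
def null_int_expression():
    """Fully null expression (independent standard-normal genes), INT'd."""
    cfg = simdata.SimConfig(
        n_individuals=200,
        n_genes=300,
        n_chromosomes=2,
        mean_tss_spacing=100_000,
        seed=101,
    )
    cat = simdata.simulate_genome(cfg)
    expr, _, _ = simdata.simulate_expression(cat, cfg)
    expr, _ = preprocess.filter_genes(expr, cat, preprocess.FilterRules())
    return preprocess.inverse_normal_transform(expr), cat


@pytest.fixture(scope="session")
def null_discovery(null_int_expression):
    expr, cat = null_int_expression
    return copcall.discover(expr, cat, R=200, fdr=0.01, seed=5)


def truth_pair_keys(dataset) -> set:
    return {
        tuple(sorted(t))
        for t in zip(dataset.truth_pairs["gene_a"], dataset.truth_pairs["gene_b"])
    }


def rng(seed=0):
    return np.random.default_rng(seed)
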