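"""Cis-eQTL mapping (nominal and permutation passes), eGene calling and
lead-eQTL sharing across gene pairs.

The association test is a simple per-variant OLS of inverse-normal
expression on alternate-allele dosage, with a two-sided t-test p-value —
the standard single-variant cis model.  The permutation pass shuffles the
phenotype across individuals and records the best association p-value per
shuffle, yielding a gene-level adjusted p-value that accounts for the number
of cis variants; a beta-distribution approximation of the null minima
(method of moments) is available for finer resolution at small permutation
counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_rng
from .genotypes import GenotypeMatrix
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "map_cis_nominal",
    "map_cis_permute",
    "call_egenes",
    "eqtl_sharing",
    "association",
]


def _cis_variants(geno: GenotypeMatrix, chrom: str, tss: int, window: int) -> np.ndarray:
    var = geno.variants
    sel = (
        (var["chrom"] == chrom)
        & (var["pos"] >= tss - window)
        & (var["pos"] <= tss + window)
    )
    return np.where(sel.to_numpy())[0]


def _assoc_stats(y: np.ndarray, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant OLS: returns (beta, two-sided p)."""
    n = len(y)
    yc = y - y.mean()
    dc = dosages - dosages.mean(axis=1, keepdims=True)
    ss_d = np.einsum("ij,ij->i", dc, dc)
    ss_y = float(yc @ yc)
    cov = dc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ss_d > 0, cov / np.where(ss_d > 0, ss_d, 1.0), 0.0)
        r = np.where(
            (ss_d > 0) & (ss_y > 0), cov / np.sqrt(np.where(ss_d > 0, ss_d, 1.0) * max(ss_y, 1e-300)), 0.0
        )
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, p


def association(
    expr: ExpressionMatrix, geno: GenotypeMatrix, gene: str, variant: str
) -> tuple[float, float]:
    """Single gene-variant OLS association (beta, two-sided p)."""
    gi = expr.gene_index()[gene]
    vi = geno.variant_index()[variant]
    beta, p = _assoc_stats(expr.values[gi], geno.dosages[[vi]].astype(float))
    return float(beta[0]), float(p[0])


def map_cis_nominal(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    catalog: pd.DataFrame,
    window: int = 1_000_000,
    p_keep: float = 0.05,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """All gene x cis-variant associations with nominal p < ``p_keep``.

    The lead variant (lowest nominal p) is retained for every gene even when
    it misses the cut, so downstream sharing always has a lead to consult.
    Variants below ``maf_min`` empirical MAF are excluded.
    """
    if expr.state != "int":
        raise ValueError("map_cis_nominal requires inverse-normal expression")
    maf_ok = geno.empirical_maf() >= maf_min
    gene_index = expr.gene_index()
    rows = []
    for rec in catalog.itertuples(index=False):
        if rec.gene_id not in gene_index:
            continue
        cis = _cis_variants(geno, rec.chrom, rec.tss, window)
        cis = cis[maf_ok[cis]]
        if len(cis) == 0:
            logger.info("gene %s has no cis variant; skipped", rec.gene_id)
            continue
        y = expr.values[gene_index[rec.gene_id]]
        beta, p = _assoc_stats(y, geno.dosages[cis].astype(float))
        lead = int(np.argmin(p))
        for k in range(len(cis)):
            if p[k] < p_keep or k == lead:
                rows.append(
                    (
                        rec.gene_id,
                        geno.variants["variant_id"].iloc[cis[k]],
                        float(beta[k]),
                        float(p[k]),
                        k == lead,
                    )
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "variant_id", "beta", "nominal_p", "is_lead"]
    )


def _beta_adjust(null_min: np.ndarray, observed: float) -> float:
    """Beta CDF at the observed minimum, Beta(a,b) fit by method of moments."""
    m = float(np.mean(null_min))
    v = float(np.var(null_min))
    if v <= 0:
        return float(observed <= m)
    common = m * (1 - m) / v - 1.0
    a, b = max(m * common, 1e-8), max((1 - m) * common, 1e-8)
    return float(np.clip(stats.beta.cdf(observed, a, b), np.finfo(float).tiny, 1.0))


def map_cis_permute(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    catalog: pd.DataFrame,
    window: int = 1_000_000,
    R: int = 1000,
    seed: int = 0,
    maf_min: float = 0.05,
    method: str = "empirical",
) -> pd.DataFrame:
    """Lead variant per gene with a permutation-adjusted p-value.

    ``method="empirical"`` uses (1 + #{null minima <= observed}) / (R + 1);
    ``method="beta"`` evaluates a method-of-moments Beta fit of the null
    minima at the observed minimum, which resolves below the empirical floor.
    Permutation RNG is derived from (seed, "eqtlperm", gene id).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if expr.state != "int":
        raise ValueError("map_cis_permute requires inverse-normal expression")
    maf_ok = geno.empirical_maf() >= maf_min
    gene_index = expr.gene_index()
    rows = []
    for rec in catalog.itertuples(index=False):
        if rec.gene_id not in gene_index:
            continue
        cis = _cis_variants(geno, rec.chrom, rec.tss, window)
        cis = cis[maf_ok[cis]]
        if len(cis) == 0:
            logger.info("gene %s has no cis variant; skipped", rec.gene_id)
            continue
        y = expr.values[gene_index[rec.gene_id]]
        dos = geno.dosages[cis].astype(float)
        beta, p = _assoc_stats(y, dos)
        lead = int(np.argmin(p))
        obs_min = float(p[lead])
        # null minima: since p is monotone in |r| at fixed dof, the minimum
        # p per permutation is the p of the maximum |correlation|
        n = len(y)
        yc = y - y.mean()
        yn = yc / max(np.linalg.norm(yc), 1e-300)
        dc = dos - dos.mean(axis=1, keepdims=True)
        dn = np.linalg.norm(dc, axis=1, keepdims=True)
        dn[dn == 0] = 1.0
        du = dc / dn
        rng = derive_rng(seed, "eqtlperm", rec.gene_id)
        max_r = np.empty(R)
        for r in range(R):
            perm = rng.permutation(n)
            max_r[r] = np.abs(du @ yn[perm]).max()
        max_r = np.clip(max_r, 0.0, 1.0)
        dof = n - 2
        t_null = max_r * np.sqrt(dof / np.maximum(1.0 - max_r**2, 1e-300))
        null_min = np.clip(2.0 * stats.t.sf(t_null, dof), np.finfo(float).tiny, 1.0)
        if method == "empirical":
            adj = (1.0 + np.sum(null_min <= obs_min)) / (R + 1.0)
        elif method == "beta":
            adj = _beta_adjust(null_min, obs_min)
        else:
            raise ValueError("method must be 'empirical' or 'beta'")
        rows.append(
            (
                rec.gene_id,
                geno.variants["variant_id"].iloc[cis[lead]],
                float(beta[lead]),
                obs_min,
                float(adj),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "variant_id", "beta", "nominal_p", "adjusted_p"]
    )


def call_egenes(leads: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg over genes' adjusted p-values; flags eGenes."""
    leads = leads.copy()
    if len(leads):
        reject, *_ = multipletests(
            leads["adjusted_p"].to_numpy(), alpha=fdr, method="fdr_bh"
        )
    else:
        reject = np.zeros(0, dtype=bool)
    leads["is_egene"] = reject
    return leads


def eqtl_sharing(
    pairs: pd.DataFrame,
    leads: pd.DataFrame,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Lead-eQTL sharing per gene pair.

    For each pair, each member that is an eGene contributes its lead variant;
    sharing counts how many of those (up to two) leads are nominally
    associated (p < 0.05) with the *partner* gene with the same effect sign.
    The partner association is always recomputed directly, so a nominal-pass
    p >= 0.05 cut never turns into missing data.  ``coexp_egenes`` counts the
    eGenes in the pair independently of sharing.
    """
    egenes = leads.loc[leads["is_egene"]].set_index("gene_id")
    gene_index = expr.gene_index()
    rows = []
    for pair in pairs.itertuples(index=False):
        a, b = sorted((pair.gene_a, pair.gene_b))
        sharing = 0
        support = []
        n_egenes = int(a in egenes.index) + int(b in egenes.index)
        for owner, partner in ((a, b), (b, a)):
            if owner not in egenes.index or partner not in gene_index:
                continue
            lead_var = egenes.loc[owner, "variant_id"]
            own_beta = float(egenes.loc[owner, "beta"])
            beta, p = association(expr, geno, partner, lead_var)
            if p < p_thresh and np.sign(beta) == np.sign(own_beta):
                sharing += 1
                support.append(f"{lead_var}:{'+' if beta > 0 else '-'}")
        rows.append((a, b, sharing, n_egenes, ";".join(support)))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "sharing", "coexp_egenes", "supporting"]
    )
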