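"""GWAS integration: trait-association counts, shared-vs-other pleiotropy
comparison and genomic-inflation (lambda) QQ analysis.

Pleiotropy of a variant is the number of traits with association p strictly
below the genome-wide threshold (5e-8).  Lambda is the median of the
chi-square(1 df) statistics implied by a p-value set divided by the
chi-square(1) median (0.45494): 1 for a well-calibrated null, above 1 when
the p-value distribution is shifted toward stronger associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_rng
from .enrich import fisher_enrichment

logger = logging.getLogger(__name__)

__all__ = [
    "CHI2_MEDIAN",
    "trait_association_counts",
    "pleiotropy_compare",
    "genomic_inflation",
    "qq_sample",
]

#: median of the chi-square distribution with one degree of freedom
CHI2_MEDIAN = 0.45494


@dataclass
class PleiotropySummary:
    mean_count_shared: float
    mean_count_other: float
    or_any_trait: float
    p_any_trait: float
    or_multi_trait: float
    p_multi_trait: float
    wilcoxon_p: float
    counts: pd.Series
    shared: pd.Series


def trait_association_counts(
    gwas: pd.DataFrame,
    variants: list | np.ndarray,
    threshold: float = 5e-8,
) -> tuple[pd.Series, list]:
    """Traits with p strictly below threshold, per queried variant.

    Variants absent from the GWAS table are reported in the missing list and
    excluded from the counts (mirrors incomplete variant coverage of real
    summary-statistics resources).
    """
    variants = list(dict.fromkeys(variants))  # unique, order-preserving
    hits = gwas.loc[gwas["pval"] < threshold]
    per_variant = hits.groupby("variant_id")["trait_id"].nunique()
    known = set(gwas["variant_id"].unique())
    missing = [v for v in variants if v not in known]
    if missing:
        logger.warning("%d of %d variants absent from the GWAS table", len(missing), len(variants))
    counts = pd.Series(
        {v: int(per_variant.get(v, 0)) for v in variants if v in known},
        dtype=int,
        name="n_traits",
    )
    return counts, missing


def pleiotropy_compare(
    counts: pd.Series,
    shared: pd.Series,
    include_zeros: bool = False,
) -> PleiotropySummary:
    """Shared vs other lead eQTLs: trait-association odds ratios and ranks.

    ``shared`` is a boolean series on the same variants ("shared" wins over
    "other" when a variant is a lead in several tissues).  Fisher tables
    compare the >=1-trait and >1-trait proportions over all variants; the
    two-sided Wilcoxon rank-sum compares counts between categories, by
    default restricted to variants associated with at least one trait.
    """
    shared = shared.reindex(counts.index).astype(bool)
    if shared.all() or (~shared).all():
        raise ValueError("need both shared and other variants")
    cs = counts[shared]
    co = counts[~shared]

    def _table(minimum: int) -> np.ndarray:
        return np.array(
            [
                [(cs >= minimum).sum(), (cs < minimum).sum()],
                [(co >= minimum).sum(), (co < minimum).sum()],
            ],
            dtype=np.int64,
        )

    any_res = fisher_enrichment(_table(1), annotation="any_trait")
    multi_res = fisher_enrichment(_table(2), annotation="multi_trait")
    ws = cs if include_zeros else cs[cs >= 1]
    wo = co if include_zeros else co[co >= 1]
    if len(ws) and len(wo):
        wilcoxon_p = float(stats.mannwhitneyu(ws, wo, alternative="two-sided").pvalue)
    else:
        wilcoxon_p = float("nan")
    return PleiotropySummary(
        mean_count_shared=float(ws.mean()) if len(ws) else float("nan"),
        mean_count_other=float(wo.mean()) if len(wo) else float("nan"),
        or_any_trait=any_res.odds_ratio,
        p_any_trait=any_res.p_value,
        or_multi_trait=multi_res.odds_ratio,
        p_multi_trait=multi_res.p_value,
        wilcoxon_p=wilcoxon_p,
        counts=counts,
        shared=shared,
    )


def genomic_inflation(pvals: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ coordinates for a p-value set.

    Returns (lambda, frame with expected/observed -log10 p sorted ascending
    in expected).  Zero p-values are clipped to the smallest positive float.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any():
        logger.warning("%d p-values <= 0 clipped", int((p <= 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_MEDIAN)
    n = p.size
    expected = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    observed = np.sort(-np.log10(p))
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    return lam, qq


def qq_sample(
    gwas: pd.DataFrame, trait: str, n: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Seed-controlled background sample of one trait's p-values for QQ plots."""
    p = gwas.loc[gwas["trait_id"] == trait, "pval"].to_numpy()
    if len(p) <= n:
        return p
    rng = derive_rng(seed, "qq", trait)
    return rng.choice(p, size=n, replace=False)
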