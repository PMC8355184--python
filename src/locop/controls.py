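"""Matched control sets: distance-matched non-COPs and correlation-matched
trans-COPs.

Because many molecular features (chromatin contacts, enhancer interactions)
decay with genomic distance, feature comparisons between co-expressed and
non-co-expressed pairs are only meaningful on a distance-matched background.
Each co-expressed pair gets one control sampled uniformly from the eligible
candidates, without replacement, iterating pairs in a seed-shuffled order so
no pair is systematically favored when candidates are scarce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .copcall import DiscoveryResult
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["MatchedControlSet", "match_noncops", "match_transcops", "trans_pair_pool"]


@dataclass
class MatchedControlSet:
    """COP/control matches with their residual discrepancy.

    ``matches`` columns: cop_a, cop_b, ctrl_a, ctrl_b, cop_value, ctrl_value,
    discrepancy.  ``unmatched`` lists COP keys for which no eligible
    candidate remained.
    """

    matches: pd.DataFrame
    unmatched: list
    seed: int

    @property
    def matched_fraction(self) -> float:
        total = len(self.matches) + len(self.unmatched)
        return len(self.matches) / total if total else float("nan")


def _greedy_match(
    cop_keys: list,
    cop_values: np.ndarray,
    cand_keys: list,
    cand_values: np.ndarray,
    window_for,
    seed: int,
    stage: str,
) -> MatchedControlSet:
    """Uniform sampling without replacement within per-COP eligibility windows."""
    rng = derive_rng(seed, stage)
    order = rng.permutation(len(cop_keys))
    sort_idx = np.argsort(cand_values)
    sorted_vals = cand_values[sort_idx]
    used = np.zeros(len(cand_keys), dtype=bool)
    rows, unmatched = [], []
    for i in order:
        lo, hi = window_for(cop_values[i])
        left = np.searchsorted(sorted_vals, lo, side="left")
        right = np.searchsorted(sorted_vals, hi, side="right")
        pool = sort_idx[left:right]
        pool = pool[~used[pool]]
        if len(pool) == 0:
            unmatched.append(cop_keys[i])
            continue
        pick = int(pool[rng.integers(len(pool))])
        used[pick] = True
        rows.append(
            (
                *cop_keys[i],
                *cand_keys[pick],
                float(cop_values[i]),
                float(cand_values[pick]),
                float(abs(cand_values[pick] - cop_values[i])),
            )
        )
    if unmatched:
        logger.warning("%d pairs had no eligible control", len(unmatched))
    matches = pd.DataFrame(
        rows,
        columns=[
            "cop_a",
            "cop_b",
            "ctrl_a",
            "ctrl_b",
            "cop_value",
            "ctrl_value",
            "discrepancy",
        ],
    )
    return MatchedControlSet(matches=matches, unmatched=unmatched, seed=seed)


def match_noncops(
    result: DiscoveryResult,
    seed: int = 0,
    max_distance_diff: int = 100,
    min_adj_p: float = 0.5,
) -> MatchedControlSet:
    """One distance-matched non-COP per COP.

    Candidates are tested pairs that are not COPs, with adjusted p > 0.5 from
    both sides (so they are not borderline pairs that merely missed the FDR
    cut) and TSS-distance discrepancy <= 100 bp.
    """
    pairs = result.pairs
    cops = pairs.loc[pairs["is_cop"]]
    cand = pairs.loc[
        ~pairs["is_cop"]
        & pairs["filtered_reason"].isna()
        & (pairs["adj_p_a"] > min_adj_p)
        & (pairs["adj_p_b"] > min_adj_p)
    ]
    if cand.empty:
        raise ValueError("empty non-COP candidate pool")
    return _greedy_match(
        list(zip(cops["gene_a"], cops["gene_b"])),
        cops["tss_distance"].to_numpy(dtype=float),
        list(zip(cand["gene_a"], cand["gene_b"])),
        cand["tss_distance"].to_numpy(dtype=float),
        lambda d: (d - max_distance_diff, d + max_distance_diff),
        seed,
        "noncop",
    )


def trans_pair_pool(
    expr: ExpressionMatrix,
    catalog: pd.DataFrame,
    result: DiscoveryResult,
    n_samples: int = 50_000,
    seed: int = 0,
    min_r: float | None = None,
) -> pd.DataFrame:
    """Random sample of cross-chromosome pairs with correlation above the
    run's minimum significant cis correlation (the trans-COP analogue pool)."""
    if min_r is None:
        cops = result.cops()
        if cops.empty:
            raise ValueError("no COPs; supply min_r explicitly")
        min_r = float(cops["pearson_r"].abs().min())
    rng = derive_rng(seed, "transpool")
    chrom = dict(zip(catalog["gene_id"], catalog["chrom"]))
    genes = [g for g in expr.genes if g in chrom]
    idx = expr.gene_index()
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    unit = centered / norms[:, None]
    rows = []
    seen = set()
    for _ in range(n_samples):
        a, b = rng.choice(len(genes), size=2, replace=False)
        ga, gb = genes[a], genes[b]
        if chrom[ga] == chrom[gb]:
            continue
        key = tuple(sorted((ga, gb)))
        if key in seen:
            continue
        seen.add(key)
        r = float(unit[idx[ga]] @ unit[idx[gb]])
        if abs(r) >= min_r:
            rows.append((*key, r))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pearson_r"])


def match_transcops(
    result: DiscoveryResult,
    trans_pool: pd.DataFrame,
    seed: int = 0,
    max_rel_diff: float = 0.05,
) -> MatchedControlSet:
    """One correlation-matched trans pair per cis-COP.

    Eligibility: relative correlation difference at most ``max_rel_diff`` of
    the cis-COP's correlation (the "5% different" rule read as relative).
    """
    cops = result.cops()
    if trans_pool.empty:
        raise ValueError("empty trans-pair pool")

    def window(r: float) -> tuple:
        lo = r * (1 - max_rel_diff), r * (1 + max_rel_diff)
        return (min(lo), max(lo))

    return _greedy_match(
        list(zip(cops["gene_a"], cops["gene_b"])),
        cops["pearson_r"].to_numpy(dtype=float),
        list(zip(trans_pool["gene_a"], trans_pool["gene_b"])),
        trans_pool["pearson_r"].to_numpy(dtype=float),
        window,
        seed,
        "transcop",
    )
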