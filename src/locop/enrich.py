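"""Enrichment tests.

Three flavours are provided:

* pair-level functional relatedness — one-sided Fisher's exact test of COP
  membership against being functionally related (same GO term, pathway,
  complex, or paralogy) over all tested pairs;
* permutation-based eQTL-annotation enrichment — the observed number of
  lead eQTLs overlapping an annotation track is compared with the mean
  overlap when gene *neighborhoods* (annotation intervals expressed as
  TSS-relative, strand-oriented offsets) are randomly reassigned among
  genes, which preserves the global annotation-around-TSS geometry while
  breaking the gene-specific assignment;
* shared-vs-other lead-eQTL overlap — two-sided Fisher comparing overlap
  rates of shared lead eQTLs against other lead eQTLs per track.

Odds ratios are the sample cross-product ratio with a 0.5 continuity
correction when a cell is empty (flagged); confidence intervals are Woolf
(log-OR normal approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_rng
from .features import IntervalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "pair_functional_enrichment",
    "eqtl_annotation_enrichment",
    "shared_vs_other_enrichment",
]


@dataclass
class EnrichmentResult:
    annotation: str
    observed: int
    expected: float
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    n_perm: int = 0
    continuity_corrected: bool = False


def _odds_ratio_ci(table: np.ndarray) -> tuple[float, float, float, bool]:
    """Cross-product OR with Woolf 95% CI; 0.5 correction on zero cells."""
    a, b = table[0]
    c, d = table[1]
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(oratio) - 1.96 * se))
    hi = float(np.exp(np.log(oratio) + 1.96 * se))
    return float(oratio), lo, hi, corrected


def fisher_enrichment(
    table: np.ndarray, annotation: str = "", alternative: str = "two-sided"
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]]."""
    table = np.asarray(table, dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative=alternative)
    oratio, lo, hi, corrected = _odds_ratio_ci(table)
    if corrected:
        logger.info("zero cell in %s table; 0.5 continuity correction applied", annotation)
    return EnrichmentResult(
        annotation=annotation,
        observed=int(table[0, 0]),
        expected=float("nan"),
        odds_ratio=oratio,
        p_value=float(p),
        ci_low=lo,
        ci_high=hi,
        continuity_corrected=corrected,
    )


def pair_functional_enrichment(
    cop_keys: set,
    tested_pairs: pd.DataFrame,
    relatedness: pd.DataFrame,
) -> dict:
    """One-sided Fisher enrichment of COPs among functionally related pairs.

    ``relatedness`` has columns gene_a, gene_b, source (one row per related
    pair per annotation source).  Returns {source: EnrichmentResult} with the
    2x2 table (COP x related) over all tested pairs.
    """
    tested = {tuple(sorted(k)) for k in zip(tested_pairs["gene_a"], tested_pairs["gene_b"])}
    cop_keys = {tuple(sorted(k)) for k in cop_keys}
    results = {}
    for source, grp in relatedness.groupby("source"):
        related = {
            tuple(sorted(k)) for k in zip(grp["gene_a"], grp["gene_b"])
        } & tested
        a = len(cop_keys & related)
        b = len(cop_keys - related)
        c = len(related - cop_keys)
        d = len(tested) - a - b - c
        res = fisher_enrichment(
            np.array([[a, b], [c, d]]), annotation=source, alternative="greater"
        )
        results[source] = res
    return results


def _neighborhoods(
    catalog: pd.DataFrame, track: IntervalTrack, window: int
) -> dict:
    """Per gene: annotation intervals within +/- window of the TSS expressed
    as strand-oriented offsets (mirrored for minus-strand genes)."""
    out = {}
    for rec in catalog.itertuples(index=False):
        hits = track.overlapping(rec.chrom, rec.tss - window, rec.tss + window)
        if rec.strand == "-":
            starts = rec.tss - hits["end"].to_numpy(np.int64)
            ends = rec.tss - hits["start"].to_numpy(np.int64)
        else:
            starts = hits["start"].to_numpy(np.int64) - rec.tss
            ends = hits["end"].to_numpy(np.int64) - rec.tss
        order = np.argsort(starts)
        out[rec.gene_id] = (starts[order], ends[order])
    return out


def _offset_in(neigh: tuple, offset: int) -> bool:
    starts, ends = neigh
    k = np.searchsorted(starts, offset, side="right")
    return bool(np.any(ends[:k] > offset))


def eqtl_annotation_enrichment(
    leads: pd.DataFrame,
    catalog: pd.DataFrame,
    track: IntervalTrack,
    n_perm: int = 10_000,
    window: int = 1_000_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed vs permutation-expected overlap of lead eQTLs with a track.

    ``leads`` needs gene_id and a variant position column ``pos`` (same
    coordinate system as the catalog); granularity is gene-eQTL pairs, so a
    variant leading two genes counts twice.  Per permutation the gene
    neighborhoods are reassigned by a random permutation of genes; the eQTL
    is overlap-tested at its TSS-relative, strand-oriented offset against
    the neighborhood it received.  The p-value is the two-sided empirical
    tail (1+r)/(1+R); the odds ratio comes from a 2x2 of observed vs rounded
    expected overlap counts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cat = catalog.set_index("gene_id")
    neigh = _neighborhoods(catalog, track, window)
    genes = list(neigh)
    gene_pos = {g: i for i, g in enumerate(genes)}
    # eQTL offsets, strand-oriented like the neighborhoods
    eqtls = []
    for rec in leads.itertuples(index=False):
        if rec.gene_id not in gene_pos:
            continue
        tss = int(cat.loc[rec.gene_id, "tss"])
        strand = cat.loc[rec.gene_id, "strand"]
        off = tss - int(rec.pos) if strand == "-" else int(rec.pos) - tss
        eqtls.append((gene_pos[rec.gene_id], off))
    total = len(eqtls)
    if total == 0:
        raise ValueError("no lead eQTLs mapped to catalog genes")
    # membership matrix: eQTL offset x candidate neighborhood
    member = np.zeros((total, len(genes)), dtype=bool)
    for i, (_, off) in enumerate(eqtls):
        for j, g in enumerate(genes):
            member[i, j] = _offset_in(neigh[g], off)
    own = np.array([gi for gi, _ in eqtls])
    observed = int(member[np.arange(total), own].sum())
    rng = derive_rng(seed, "fenrich")
    null = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(len(genes))
        null[r] = member[np.arange(total), perm[own]].sum()
    expected = float(null.mean())
    p_hi = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    p_lo = (1.0 + np.sum(null <= observed)) / (n_perm + 1.0)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    exp_in = int(round(expected))
    table = np.array(
        [[observed, total - observed], [exp_in, total - exp_in]], dtype=np.int64
    )
    oratio, lo, hi, corrected = _odds_ratio_ci(table)
    return EnrichmentResult(
        annotation=track.name,
        observed=observed,
        expected=expected,
        odds_ratio=oratio,
        p_value=float(p),
        ci_low=lo,
        ci_high=hi,
        n_perm=n_perm,
        continuity_corrected=corrected,
    )


def _overlap_count(leads: pd.DataFrame, track: IntervalTrack) -> int:
    n = 0
    for rec in leads.itertuples(index=False):
        n += track.count_overlapping(rec.chrom, int(rec.pos), int(rec.pos) + 1) > 0
    return int(n)


def shared_vs_other_enrichment(
    shared_leads: pd.DataFrame,
    other_leads: pd.DataFrame,
    tracks: dict,
) -> dict:
    """Two-sided Fisher of (shared vs other lead eQTLs) x (overlap vs not).

    Lead frames need chrom and pos columns.  Returns {track: result}.
    """
    if shared_leads.empty or other_leads.empty:
        raise ValueError("both eQTL sets must be nonempty")
    results = {}
    for name, track in tracks.items():
        a = _overlap_count(shared_leads, track)
        c = _overlap_count(other_leads, track)
        table = np.array(
            [[a, len(shared_leads) - a], [c, len(other_leads) - c]], dtype=np.int64
        )
        res = fisher_enrichment(table, annotation=name, alternative="two-sided")
        results[name] = res
    return results
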