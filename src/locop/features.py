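"""Pair-level molecular-feature metrics.

Each metric is symmetric in the two genes of a pair and zero-filled when the
underlying annotation is missing, so the assembled feature table never
contains missing values.  Coordinates are 0-based half-open internally (BED
native); "between the TSSs" means the open interval (min TSS, max TSS) and
an interval counts as present there on any intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntervalTrack",
    "FEATURE_COLUMNS",
    "ctcf_metrics",
    "hic_contact",
    "enhancer_metrics",
    "tfbs_metrics",
    "expression_similarity",
    "ld_proxy",
    "go_sharing",
    "assemble_features",
]

FEATURE_COLUMNS = [
    "total_ctcf",
    "inverted_ctcf",
    "hic_contact",
    "enh_sharing",
    "enh_total",
    "tf_shared",
    "tfbs_total",
    "diff_expr_level",
    "diff_coef_var",
    "go_sharing",
    "ld_proxy",
    "eqtl_sharing",
    "coexp_egenes",
]


@dataclass
class IntervalTrack:
    """Named interval set, sorted per chromosome for fast overlap counting."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end, strand, label
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals require start < end")
        for chrom, grp in df.groupby("chrom"):
            g = grp.sort_values("start")
            self._by_chrom[chrom] = {
                "starts": g["start"].to_numpy(np.int64),
                "ends_sorted": np.sort(g["end"].to_numpy(np.int64)),
                "ends": g["end"].to_numpy(np.int64),
                "strands": g["strand"].to_numpy(object),
                "labels": g["label"].to_numpy(object),
            }

    def count_overlapping(self, chrom: str, lo: int, hi: int) -> int:
        """Number of intervals intersecting the open interval (lo, hi)."""
        d = self._by_chrom.get(chrom)
        if d is None or hi <= lo:
            return 0
        n_start = np.searchsorted(d["starts"], hi, side="left")
        n_end = np.searchsorted(d["ends_sorted"], lo, side="right")
        return int(n_start - n_end)

    def overlapping(self, chrom: str, lo: int, hi: int) -> pd.DataFrame:
        d = self._by_chrom.get(chrom)
        if d is None or hi <= lo:
            return pd.DataFrame(columns=["start", "end", "strand", "label"])
        mask = (d["starts"] < hi) & (d["ends"] > lo)
        return pd.DataFrame(
            {
                "start": d["starts"][mask],
                "end": d["ends"][mask],
                "strand": d["strands"][mask],
                "label": d["labels"][mask],
            }
        )


def _pair_tss(pair, catalog_idx) -> tuple:
    a = catalog_idx[pair[0]]
    b = catalog_idx[pair[1]]
    if a[0] != b[0]:
        raise ValueError("pair genes must share a chromosome")
    return a[0], int(a[1]), int(b[1])


def ctcf_metrics(
    pair: tuple,
    ctcf_sites: IntervalTrack | None,
    ctcf_motifs: IntervalTrack | None,
    catalog_idx: dict,
) -> tuple[int, int]:
    """(total CTCF sites between the TSSs, opposite-orientation motif pairs).

    The inverted count is n+ * n- over oppositely oriented motifs in the
    inter-TSS interval: every (+, -) pairing is a potential loop anchor pair.
    """
    chrom, ta, tb = _pair_tss(pair, catalog_idx)
    lo, hi = min(ta, tb), max(ta, tb)
    total = ctcf_sites.count_overlapping(chrom, lo, hi) if ctcf_sites else 0
    inverted = 0
    if ctcf_motifs is not None:
        motifs = ctcf_motifs.overlapping(chrom, lo, hi)
        n_plus = int((motifs["strand"] == "+").sum())
        n_minus = int((motifs["strand"] == "-").sum())
        inverted = n_plus * n_minus
    return total, inverted


def hic_contact(
    pair: tuple,
    contacts: dict | None,
    catalog_idx: dict,
    resolution: int = 5000,
) -> float:
    """Normalised contact count between the 5 kb bins holding the two TSSs.

    ``contacts`` maps (chrom, bin1_start, bin2_start) with bin1 <= bin2 to a
    value; missing bin pairs are zero.
    """
    if contacts is None:
        return 0.0
    chrom, ta, tb = _pair_tss(pair, catalog_idx)
    b1 = (min(ta, tb) // resolution) * resolution
    b2 = (max(ta, tb) // resolution) * resolution
    return float(contacts.get((chrom, b1, b2), 0.0))


def enhancer_metrics(pair: tuple, links: dict | None) -> tuple[int, int]:
    """(shared enhancers, distinct enhancers) for the pair.

    ``links`` maps gene id -> set of enhancer ids.  An enhancer interacting
    with both genes counts once in the total (set union).
    """
    if links is None:
        return 0, 0
    ea = links.get(pair[0], set())
    eb = links.get(pair[1], set())
    return len(ea & eb), len(ea | eb)


def tfbs_metrics(
    pair: tuple,
    motifs: IntervalTrack | None,
    catalog_idx: dict,
    flank: int = 50_000,
) -> tuple[int, int]:
    """(shared TF motif ids, total motif occurrences) in TSS +/- flank windows.

    The total sums occurrences per window, so a motif instance overlapping
    both windows contributes twice.
    """
    if motifs is None:
        return 0, 0
    chrom, ta, tb = _pair_tss(pair, catalog_idx)
    wa = motifs.overlapping(chrom, ta - flank, ta + flank)
    wb = motifs.overlapping(chrom, tb - flank, tb + flank)
    shared = len(set(wa["label"]) & set(wb["label"]))
    return shared, len(wa) + len(wb)


def expression_similarity(
    pair: tuple, summaries: pd.DataFrame | None
) -> tuple[float, float]:
    """Relative differences of expression level and of coefficient of variation.

    diff = |m_a - m_b| / mean(m_a, m_b) on raw-scale per-gene summaries
    (columns ``level`` and ``cv``).
    """
    if summaries is None:
        return 0.0, 0.0

    def _rel(a: float, b: float, what: str) -> float:
        denom = (a + b) / 2.0
        if denom == 0:
            warnings.warn(f"zero mean {what} for pair {pair}", stacklevel=3)
            return 0.0
        return abs(a - b) / denom

    try:
        sa = summaries.loc[pair[0]]
        sb = summaries.loc[pair[1]]
    except KeyError:
        return 0.0, 0.0
    level = _rel(float(sa["level"]), float(sb["level"]), "expression level")
    cv = _rel(float(sa["cv"]), float(sb["cv"]), "coefficient of variation")
    return level, cv


def expression_summaries(
    raw_values: np.ndarray, genes: np.ndarray, stat: str = "mean"
) -> pd.DataFrame:
    """Per-gene raw-scale level and coefficient of variation."""
    if stat == "mean":
        level = raw_values.mean(axis=1)
    elif stat == "median":
        level = np.median(raw_values, axis=1)
    else:
        raise ValueError("stat must be 'mean' or 'median'")
    sd = raw_values.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = raw_values.mean(axis=1)
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    return pd.DataFrame({"level": level, "cv": cv}, index=pd.Index(genes))


def ld_proxy(
    pair: tuple,
    genotypes,
    catalog_idx: dict,
    flank: int = 5000,
) -> float:
    """Maximum dosage r^2 between variants flanking the two TSSs (+/- 5 kb)."""
    if genotypes is None:
        return 0.0
    chrom, ta, tb = _pair_tss(pair, catalog_idx)
    var = genotypes.variants
    near = var["chrom"] == chrom
    pos = var["pos"]
    sel_a = near & (pos >= ta - flank) & (pos <= ta + flank)
    sel_b = near & (pos >= tb - flank) & (pos <= tb + flank)
    if not sel_a.any() or not sel_b.any():
        return 0.0
    da = genotypes.dosages[sel_a.to_numpy()].astype(float)
    db = genotypes.dosages[sel_b.to_numpy()].astype(float)

    def _standardize(d: np.ndarray) -> np.ndarray:
        c = d - d.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(c, axis=1, keepdims=True)
        keep = norms[:, 0] > 0  # monomorphic variants carry no LD information
        return c[keep] / norms[keep]

    ua, ub = _standardize(da), _standardize(db)
    if not len(ua) or not len(ub):
        return 0.0
    r = ua @ ub.T
    return float(np.max(r**2))


def go_sharing(pair: tuple, terms: dict | None) -> int:
    """Number of exactly matching functional terms between the two genes."""
    if terms is None:
        return 0
    return len(terms.get(pair[0], set()) & terms.get(pair[1], set()))


def assemble_features(
    pairs: pd.DataFrame,
    catalog: pd.DataFrame,
    *,
    labels: np.ndarray | None = None,
    ctcf_sites: IntervalTrack | None = None,
    ctcf_motifs: IntervalTrack | None = None,
    tf_motifs: IntervalTrack | None = None,
    enhancer_links: pd.DataFrame | None = None,
    hic: pd.DataFrame | None = None,
    raw_summaries: pd.DataFrame | None = None,
    genotypes=None,
    go_terms: pd.DataFrame | None = None,
    eqtl_sharing: pd.DataFrame | None = None,
    tf_flank: int = 50_000,
    ld_flank: int = 5000,
    hic_resolution: int = 5000,
) -> pd.DataFrame:
    """One zero-filled feature row per pair, deterministic column order.

    ``pairs`` needs gene_a/gene_b (and tss_distance if present it is carried
    through); ``labels`` is the 0/1 co-expression label column.  Any omitted
    annotation source yields zeros for its metrics.
    """
    keys = list(zip(pairs["gene_a"], pairs["gene_b"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate pair rows")
    catalog_idx = {
        r.gene_id: (r.chrom, r.tss) for r in catalog.itertuples(index=False)
    }
    links = None
    if enhancer_links is not None:
        links = {}
        for row in enhancer_links.itertuples(index=False):
            links.setdefault(row.gene_id, set()).add(row.enhancer_id)
    contacts = None
    if hic is not None:
        contacts = {
            (r.chrom, int(r.bin1_start), int(r.bin2_start)): float(r.count)
            for r in hic.itertuples(index=False)
        }
    terms = None
    if go_terms is not None:
        terms = {}
        for row in go_terms.itertuples(index=False):
            terms.setdefault(row.gene_id, set()).add(row.go_id)
    share_map = {}
    if eqtl_sharing is not None:
        for row in eqtl_sharing.itertuples(index=False):
            share_map[tuple(sorted((row.gene_a, row.gene_b)))] = (
                int(row.sharing),
                int(row.coexp_egenes),
            )

    rows = []
    for pair in keys:
        total_ctcf, inverted = ctcf_metrics(pair, ctcf_sites, ctcf_motifs, catalog_idx)
        contact = hic_contact(pair, contacts, catalog_idx, resolution=hic_resolution)
        enh_share, enh_total = enhancer_metrics(pair, links)
        tf_shared, tfbs_total = tfbs_metrics(pair, tf_motifs, catalog_idx, flank=tf_flank)
        lvl, cv = expression_similarity(pair, raw_summaries)
        ld = ld_proxy(pair, genotypes, catalog_idx, flank=ld_flank)
        go = go_sharing(pair, terms)
        sharing, egenes = share_map.get(tuple(sorted(pair)), (0, 0))
        rows.append(
            (
                total_ctcf,
                inverted,
                contact,
                enh_share,
                enh_total,
                tf_shared,
                tfbs_total,
                lvl,
                cv,
                go,
                ld,
                sharing,
                egenes,
            )
        )
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    table.insert(0, "gene_a", pairs["gene_a"].to_numpy())
    table.insert(1, "gene_b", pairs["gene_b"].to_numpy())
    if "tss_distance" in pairs.columns:
        table["tss_distance"] = pairs["tss_distance"].to_numpy()
    if labels is not None:
        table["label"] = np.asarray(labels, dtype=int)
    return table.fillna(0.0)
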