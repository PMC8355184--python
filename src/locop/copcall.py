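"""Local co-expression discovery via per-gene permutation nulls.

For every gene, the observed Pearson correlations with all genes whose TSSs
lie within a cis window are compared against a null distribution built by
shuffling that gene's expression values across individuals while keeping the
cis genes intact.  Each shuffle records the *highest* correlation across the
cis set, which automatically adjusts for the number of neighbours a gene has
and preserves the correlation structure among them.  The empirical tail
probability of the observed pair correlation against these null maxima is
the pair's "adjusted p-value" from that gene's side.  Benjamini-Hochberg is
then applied across genes on each gene's best adjusted p-value, and a pair
is called co-expressed (a COP) when its adjusted p-value from *both* member
genes passes the BH-derived global threshold.

Conventions (documented because permutation tests have free choices):

* correlation statistic defaults to |r| (two-sided null) so both positive
  and negative co-expression is detectable; ``statistic="signed"`` restricts
  the null to the upper tail.
* empirical p = (1 + #{null maxima >= |r_obs|}) / (R + 1); ties count toward
  the null (conservative, never zero).
* per-gene RNG seeds derive from (global seed, "copcall", gene id), so
  results are independent of gene iteration order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_rng
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullRecord",
    "DiscoveryResult",
    "enumerate_cis_pairs",
    "gene_null",
    "call_cops",
    "discover",
    "apply_pair_filters",
    "build_components",
    "tissue_sharing",
]

PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "chrom",
    "tss_distance",
    "pearson_r",
    "adj_p_a",
    "adj_p_b",
    "is_cop",
    "filtered_reason",
]


@dataclass
class NullRecord:
    """Per-gene permutation null: R maxima of the statistic over the cis set."""

    gene_id: str
    n_perm: int
    null_maxima: np.ndarray
    best_obs: float
    gene_adj_p: float


@dataclass
class DiscoveryResult:
    """Pair table, per-gene nulls and the BH-derived global threshold."""

    pairs: pd.DataFrame
    nulls: dict
    threshold: float
    fdr: float
    settings: dict = field(default_factory=dict)

    def cops(self) -> pd.DataFrame:
        return self.pairs.loc[self.pairs["is_cop"]].reset_index(drop=True)


def enumerate_cis_pairs(catalog: pd.DataFrame, window: int = 1_000_000) -> pd.DataFrame:
    """All unordered same-chromosome gene pairs with TSS distance < window.

    Pairs are canonical (gene_a < gene_b by id) and listed once.
    """
    rows = []
    for chrom, grp in catalog.groupby("chrom", sort=True):
        g = grp.sort_values("tss")
        ids = g["gene_id"].to_numpy()
        tss = g["tss"].to_numpy(dtype=np.int64)
        for i in range(len(g)):
            j = i + 1
            while j < len(g) and tss[j] - tss[i] < window:
                a, b = sorted((ids[i], ids[j]))
                rows.append((a, b, chrom, int(tss[j] - tss[i])))
                j += 1
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "chrom", "tss_distance"])


def _unit_rows(values: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm, so r(g,h) = U_g . U_h."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    constant = norms[:, 0] == 0
    norms[constant] = 1.0
    out = centered / norms
    return out


def gene_null(
    expr: ExpressionMatrix,
    gene: str,
    cis_set: list,
    R: int,
    seed: int,
    statistic: str = "abs",
    _unit: np.ndarray | None = None,
    _index: dict | None = None,
) -> tuple[NullRecord, pd.DataFrame]:
    """Permutation null for one focal gene against its cis set.

    Returns the null record and a frame of per-pair adjusted p-values
    (columns gene_a/gene_b canonical, obs_r, adj_p), where adj_p is computed
    from *this* gene's null.  ``_unit``/``_index`` allow :func:`discover` to
    share the precomputed unit-row matrix; external callers can ignore them.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if len(cis_set) < 1:
        raise ValueError("cis_set must be nonempty")
    if expr.state != "int":
        raise ValueError("gene_null requires inverse-normal-transformed expression")
    unit = _unit if _unit is not None else _unit_rows(expr.values)
    index = _index if _index is not None else expr.gene_index()
    gi = index[gene]
    ci = np.array([index[h] for h in cis_set])
    focal = unit[gi]
    if not np.any(focal):
        warnings.warn(f"gene {gene!r} is constant; adjusted p set to 1", stacklevel=2)
        obs = np.zeros(len(ci))
        null_max = np.zeros(R)
    else:
        cis_mat = unit[ci]
        obs = cis_mat @ focal
        rng = derive_rng(seed, "copcall", gene)
        n = len(focal)
        null_max = np.empty(R)
        stat = np.abs if statistic == "abs" else (lambda x: x)
        for r in range(R):
            perm = rng.permutation(n)
            null_max[r] = stat(cis_mat @ focal[perm]).max()
    stat_obs = np.abs(obs) if statistic == "abs" else obs
    # empirical tail: (1 + #{null >= obs}) / (R + 1), ties toward the null
    counts = (null_max[None, :] >= stat_obs[:, None]).sum(axis=1)
    adj_p = (1.0 + counts) / (R + 1.0)
    best = int(np.argmax(stat_obs))
    record = NullRecord(
        gene_id=gene,
        n_perm=R,
        null_maxima=null_max,
        best_obs=float(stat_obs[best]),
        gene_adj_p=float(adj_p[best]),
    )
    rows = []
    for k, h in enumerate(cis_set):
        a, b = sorted((gene, h))
        rows.append((a, b, float(obs[k]), float(adj_p[k])))
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "obs_r", "adj_p"])
    frame["from_gene"] = gene
    return record, frame


def call_cops(
    pairs: pd.DataFrame,
    nulls: dict,
    fdr: float = 0.01,
    r_artifact: float = 0.99,
) -> DiscoveryResult:
    """Call co-expressed pairs from per-gene nulls via BH on gene-level p.

    ``pairs`` must carry pearson_r, adj_p_a and adj_p_b columns.  Pairs with
    |r| >= ``r_artifact`` are flagged as artifacts and removed *before* the
    BH step (their adjusted p-values do not contribute gene-level minima:
    gene-level p is recomputed from the surviving pairs).
    """
    pairs = pairs.copy()
    pairs["filtered_reason"] = pd.array([None] * len(pairs), dtype="object")
    artifact = pairs["pearson_r"].abs() >= r_artifact
    pairs.loc[artifact, "filtered_reason"] = "artifact"
    if artifact.any():
        logger.info("removed %d artifact pairs (|r| >= %.2f)", artifact.sum(), r_artifact)

    live = pairs.loc[~artifact]
    # gene-level adjusted p = min over the gene's surviving pairs of the
    # adjusted p computed from that gene's own null
    gene_p: dict[str, float] = {}
    for col_gene, col_p in (("gene_a", "adj_p_a"), ("gene_b", "adj_p_b")):
        grp = live.groupby(col_gene)[col_p].min()
        for g, p in grp.items():
            gene_p[g] = min(p, gene_p.get(g, np.inf))
    genes = sorted(gene_p)
    pvec = np.array([gene_p[g] for g in genes])
    if len(pvec):
        reject, *_ = multipletests(pvec, alpha=fdr, method="fdr_bh")
    else:
        reject = np.zeros(0, dtype=bool)
    if reject.any():
        threshold = float(pvec[reject].max())
    else:
        threshold = float("nan")
        logger.info("no gene passes BH at FDR %.3g; zero COPs", fdr)

    is_cop = (
        ~artifact
        & (pairs["adj_p_a"] <= threshold)
        & (pairs["adj_p_b"] <= threshold)
        if np.isfinite(threshold)
        else pd.Series(False, index=pairs.index)
    )
    pairs["is_cop"] = is_cop.to_numpy()
    return DiscoveryResult(pairs=pairs, nulls=nulls, threshold=threshold, fdr=fdr)


def discover(
    expr: ExpressionMatrix,
    catalog: pd.DataFrame,
    window: int = 1_000_000,
    R: int = 1000,
    fdr: float = 0.01,
    seed: int = 0,
    statistic: str = "abs",
    r_artifact: float = 0.99,
) -> DiscoveryResult:
    """End-to-end discovery: enumerate cis pairs, build per-gene nulls, call."""
    catalog = catalog[catalog["gene_id"].isin(set(expr.genes))]
    pair_df = enumerate_cis_pairs(catalog, window=window)
    if pair_df.empty:
        return DiscoveryResult(
            pairs=pair_df.assign(
                pearson_r=[], adj_p_a=[], adj_p_b=[], is_cop=[], filtered_reason=[]
            ),
            nulls={},
            threshold=float("nan"),
            fdr=fdr,
            settings={"window": window, "R": R, "seed": seed, "statistic": statistic},
        )
    # per-gene cis sets
    cis_sets: dict[str, list] = {}
    for row in pair_df.itertuples(index=False):
        cis_sets.setdefault(row.gene_a, []).append(row.gene_b)
        cis_sets.setdefault(row.gene_b, []).append(row.gene_a)

    unit = _unit_rows(expr.values)
    index = expr.gene_index()
    nulls: dict[str, NullRecord] = {}
    adj: dict[tuple, dict] = {}
    obs_r: dict[tuple, float] = {}
    for gene in sorted(cis_sets):
        record, frame = gene_null(
            expr, gene, cis_sets[gene], R, seed, statistic, _unit=unit, _index=index
        )
        nulls[gene] = record
        for row in frame.itertuples(index=False):
            key = (row.gene_a, row.gene_b)
            obs_r[key] = row.obs_r
            adj.setdefault(key, {})[row.from_gene] = row.adj_p
    pair_df = pair_df.copy()
    pair_df["pearson_r"] = [
        obs_r[(a, b)] for a, b in zip(pair_df["gene_a"], pair_df["gene_b"])
    ]
    pair_df["adj_p_a"] = [
        adj[(a, b)][a] for a, b in zip(pair_df["gene_a"], pair_df["gene_b"])
    ]
    pair_df["adj_p_b"] = [
        adj[(a, b)][b] for a, b in zip(pair_df["gene_a"], pair_df["gene_b"])
    ]
    result = call_cops(pair_df, nulls, fdr=fdr, r_artifact=r_artifact)
    result.settings = {"window": window, "R": R, "seed": seed, "statistic": statistic}
    return result


def apply_pair_filters(
    result: DiscoveryResult,
    paralog_pairs: pd.DataFrame | None = None,
    keep_sign: str = "positive",
) -> DiscoveryResult:
    """Drop paralog COPs and (by default) negatively correlated COPs.

    Filtered pairs keep their rows but lose the COP flag and gain a
    filtered_reason of "paralog" or "negative".
    """
    pairs = result.pairs.copy()
    paralog_keys = set()
    if paralog_pairs is not None and len(paralog_pairs):
        paralog_keys = {
            tuple(sorted((a, b)))
            for a, b in zip(paralog_pairs["gene_a"], paralog_pairs["gene_b"])
        }
    n_paralog = n_negative = 0
    for i in pairs.index[pairs["is_cop"]]:
        key = (pairs.at[i, "gene_a"], pairs.at[i, "gene_b"])
        if key in paralog_keys:
            pairs.at[i, "is_cop"] = False
            pairs.at[i, "filtered_reason"] = "paralog"
            n_paralog += 1
        elif keep_sign == "positive" and pairs.at[i, "pearson_r"] < 0:
            pairs.at[i, "is_cop"] = False
            pairs.at[i, "filtered_reason"] = "negative"
            n_negative += 1
    logger.info("pair filters removed %d paralog and %d negative COPs", n_paralog, n_negative)
    return DiscoveryResult(
        pairs=pairs,
        nulls=result.nulls,
        threshold=result.threshold,
        fdr=result.fdr,
        settings=dict(result.settings),
    )


def build_components(result: DiscoveryResult) -> tuple[pd.DataFrame, dict]:
    """Connected components of the COP graph (genes = nodes, COPs = edges).

    Returns a per-component summary and a gene -> component id mapping.
    """
    graph = nx.Graph()
    for row in result.cops().itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b)
    rows = []
    membership: dict[str, int] = {}
    for cid, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    ):
        sub = graph.subgraph(comp)
        rows.append((cid, len(comp), sub.number_of_edges()))
        for g in comp:
            membership[g] = cid
    table = pd.DataFrame(rows, columns=["component_id", "n_genes", "n_edges"])
    return table, membership


def tissue_sharing(
    results: dict,
    presence: pd.DataFrame,
    min_tissues: int = 5,
    specific_ceiling: float = 0.15,
    conserved_floor: float = 0.50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tissue COP sharing matrix and per-pair prevalence categories.

    ``results`` maps tissue -> DiscoveryResult; ``presence`` is a boolean
    frame indexed by "geneA|geneB" pair keys with one column per tissue,
    true when both genes passed the expression filter there.

    The sharing matrix is non-symmetric: entry (A, B) is the percentage of
    tissue-A COPs, among those assessed in B, that are also COPs in B.
    Categories (unique / specific / prevalent / conserved) are the ratio of
    COP tissues to co-present tissues, computed only for pairs co-present in
    at least ``min_tissues`` tissues.
    """
    if len(results) < 2:
        raise ValueError("need at least two tissue results")
    tissues = list(results)
    cop_keys = {
        t: {
            f"{a}|{b}"
            for a, b in zip(results[t].cops()["gene_a"], results[t].cops()["gene_b"])
        }
        for t in tissues
    }
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for ta in tissues:
        for tb in tissues:
            if ta == tb:
                mat.loc[ta, tb] = 100.0
                continue
            assessed = [
                k
                for k in cop_keys[ta]
                if k in presence.index and presence.loc[k, tb]
            ]
            if assessed:
                hit = sum(k in cop_keys[tb] for k in assessed)
                mat.loc[ta, tb] = 100.0 * hit / len(assessed)

    all_cop_keys = set().union(*cop_keys.values())
    rows = []
    for key in sorted(all_cop_keys):
        if key not in presence.index:
            continue
        present = presence.loc[key]
        n_present = int(present.sum())
        n_cop = sum(key in cop_keys[t] and present[t] for t in tissues)
        if n_present < min_tissues:
            logger.info("pair %s co-present in %d < %d tissues; uncategorized", key, n_present, min_tissues)
            continue
        ratio = n_cop / n_present
        if n_cop == 1:
            cat = "unique"
        elif ratio > conserved_floor:
            cat = "conserved"
        elif ratio > specific_ceiling:
            cat = "prevalent"
        else:
            cat = "specific"
        rows.append((key, n_cop, n_present, ratio, cat))
    cats = pd.DataFrame(
        rows, columns=["pair", "n_cop_tissues", "n_present_tissues", "ratio", "category"]
    )
    return mat, cats
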