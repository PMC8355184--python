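"""Expression preprocessing: gene filtering, covariate residualization and
rank-based inverse normal transformation.

The expression container tracks a processing state so that downstream stages
can assert their inputs went through the expected pipeline:
``raw -> filtered -> residualized -> int`` (the residualization step may be
skipped when no covariates are used).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

STATES = ("raw", "filtered", "residualized", "int")

#: allowed state transitions (from -> allowed targets)
_TRANSITIONS = {
    "raw": {"filtered"},
    "filtered": {"residualized", "int"},
    "residualized": {"int"},
    "int": set(),
}


@dataclass
class ExpressionMatrix:
    """Genes x individuals expression values with a processing-state flag.

    Parameters
    ----------
    genes : array of gene ids (rows).
    samples : array of sample ids (columns).
    values : float matrix, shape (n_genes, n_samples).
    state : one of ``raw``, ``filtered``, ``residualized``, ``int``.
    """

    genes: np.ndarray
    samples: np.ndarray
    values: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: str = "raw") -> "ExpressionMatrix":
        return cls(
            genes=df.index.to_numpy(dtype=object),
            samples=df.columns.to_numpy(dtype=object),
            values=df.to_numpy(dtype=float),
            state=state,
        )

    def _advance(self, new_state: str, values: np.ndarray | None = None,
                 genes: np.ndarray | None = None) -> "ExpressionMatrix":
        if new_state not in _TRANSITIONS[self.state]:
            raise ValueError(
                f"illegal state transition {self.state!r} -> {new_state!r}"
            )
        return replace(
            self,
            state=new_state,
            values=self.values if values is None else values,
            genes=self.genes if genes is None else genes,
        )


@dataclass
class FilterRules:
    """Gene-level filtering rules applied before co-expression discovery.

    ``zero_fraction_ceiling``: genes with at least this fraction of zero
    measurements are removed (bulk RNA-seq convention: a gene absent in half
    the cohort is not quantifiable for correlation analysis).
    ``tpm_threshold``/``tpm_fraction``: keep genes with expression above the
    threshold in at least the given fraction of samples (optional).
    ``excluded_regions``: (chrom, start, end) intervals; genes whose TSS falls
    inside are removed (e.g. the MHC region, where mapping artifacts inflate
    correlations).
    """

    biotypes: tuple = ("protein_coding", "lincRNA")
    excluded_regions: list = field(default_factory=list)
    excluded_chroms: tuple = ()
    zero_fraction_ceiling: float = 0.5
    tpm_threshold: float | None = None
    tpm_fraction: float = 0.2
    read_threshold: float | None = None
    read_fraction: float = 0.2

    def __post_init__(self) -> None:
        for frac in (self.zero_fraction_ceiling, self.tpm_fraction, self.read_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("filter fractions must be in [0, 1]")


def filter_genes(
    expr: ExpressionMatrix,
    catalog: pd.DataFrame,
    rules: FilterRules,
    read_counts: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply biotype, region, chromosome and expression-level filters.

    Returns the filtered matrix (state ``filtered``) and a removal log with
    one (gene_id, reason) row per removed gene; the first failing rule wins.
    """
    if expr.state != "raw":
        raise ValueError(f"filter_genes expects state 'raw', got {expr.state!r}")
    cat = catalog.set_index("gene_id")
    keep = []
    removed: list[tuple[str, str]] = []
    for i, gene in enumerate(expr.genes):
        reason = None
        if gene not in cat.index:
            reason = "not_in_catalog"
        else:
            row = cat.loc[gene]
            if rules.biotypes and row["biotype"] not in rules.biotypes:
                reason = "biotype"
            elif row["chrom"] in rules.excluded_chroms:
                reason = "chromosome"
            else:
                for chrom, start, end in rules.excluded_regions:
                    if row["chrom"] == chrom and start <= row["tss"] < end:
                        reason = "excluded_region"
                        break
        if reason is None:
            vals = expr.values[i]
            if np.mean(vals == 0.0) >= rules.zero_fraction_ceiling:
                reason = "zero_fraction"
            elif rules.tpm_threshold is not None and (
                np.mean(vals > rules.tpm_threshold) < rules.tpm_fraction
            ):
                reason = "tpm_threshold"
            elif rules.read_threshold is not None and read_counts is not None:
                rc = read_counts.loc[gene].to_numpy(dtype=float)
                if np.mean(rc >= rules.read_threshold) < rules.read_fraction:
                    reason = "read_threshold"
        if reason is None:
            keep.append(i)
        else:
            removed.append((gene, reason))
    if not keep:
        raise ValueError("no genes survive filtering")
    log = pd.DataFrame(removed, columns=["gene_id", "reason"])
    out = expr._advance(
        "filtered", values=expr.values[keep], genes=expr.genes[keep]
    )
    return out, log


def residualize(expr: ExpressionMatrix, covariates: pd.DataFrame | np.ndarray) -> ExpressionMatrix:
    """Replace each gene's values by OLS residuals on the covariates.

    An intercept is always included, so residuals are centered.  Collinear
    covariate columns are dropped with a warning (rank-deficient designs
    otherwise make the fit ambiguous).  With zero covariates this reduces to
    per-gene centering.
    """
    if expr.state != "filtered":
        raise ValueError(f"residualize expects state 'filtered', got {expr.state!r}")
    cov = (
        covariates.to_numpy(dtype=float)
        if isinstance(covariates, pd.DataFrame)
        else np.asarray(covariates, dtype=float)
    )
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.size and cov.shape[0] != expr.n_samples:
        raise ValueError("covariate rows must align with samples")
    if cov.size and cov.shape[1] >= expr.n_samples:
        raise ValueError("need fewer covariates than samples")

    n = expr.n_samples
    design = np.column_stack([np.ones(n)] + ([cov] if cov.size else []))
    # drop collinear columns via rank-revealing QR on the centered design
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    indep = diag > tol
    if not indep.all():
        warnings.warn(
            f"dropping {np.sum(~indep)} collinear covariate column(s)",
            stacklevel=2,
        )
        design = design[:, indep]
    beta, *_ = np.linalg.lstsq(design, expr.values.T, rcond=None)
    resid = expr.values - (design @ beta).T
    return expr._advance("residualized", values=resid)


def expression_pcs(expr: ExpressionMatrix, n_pcs: int) -> pd.DataFrame:
    """Top principal-component sample scores of the gene-standardized matrix.

    Used as hidden-factor covariates (the deterministic analogue of factor
    models such as PEER).  Returns a samples x n_pcs frame; columns are
    mutually orthogonal.
    """
    if expr.state != "filtered":
        raise ValueError(f"expression_pcs expects state 'filtered', got {expr.state!r}")
    if n_pcs == 0:
        return pd.DataFrame(index=pd.Index(expr.samples))
    if n_pcs >= min(expr.n_genes, expr.n_samples):
        raise ValueError("n_pcs must be < min(n_genes, n_samples)")
    vals = expr.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    # SVD of genes x samples; right singular vectors are sample scores
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = (vt[:n_pcs] * s[:n_pcs, None]).T
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return pd.DataFrame(scores, index=pd.Index(expr.samples), columns=cols)


def inverse_normal_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map each gene's values rank-wise onto standard-normal quantiles.

    Uses the rank/(n+1) quantile convention with average ranks for ties, so
    tied inputs map to equal outputs and no value hits the distribution tails
    exactly.  Constant genes become all-zero (warning).  The transform is
    idempotent because it only depends on ranks.
    """
    if expr.state not in ("filtered", "residualized"):
        raise ValueError(
            f"inverse_normal_transform expects state 'filtered' or "
            f"'residualized', got {expr.state!r}"
        )
    n = expr.n_samples
    out = np.empty_like(expr.values)
    for i in range(expr.n_genes):
        vals = expr.values[i]
        if np.all(vals == vals[0]):
            warnings.warn(
                f"gene {expr.genes[i]!r} is constant; INT output set to zero",
                stacklevel=2,
            )
            out[i] = 0.0
        else:
            ranks = rankdata(vals, method="average")
            out[i] = ndtri(ranks / (n + 1))
    return expr._advance("int", values=out)
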