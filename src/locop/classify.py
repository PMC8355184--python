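"""Logistic-regression ROC-AUC harness for molecular-feature models.

For each of ``reps`` repetitions, gene pairs are split 80/20 with class
balance preserved, an unregularized logistic regression (features
standardized on the training fold) is fit on the training pairs, and the ROC
AUC is measured on the held-out pairs.  The mean over repetitions is the
reported score for a model.  Related metrics are grouped into named models
exactly as they enter the analysis (e.g. the CTCF model = total sites +
inverted motifs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from ._seeds import derive_rng

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "AucResult", "MODEL_SPECS", "evaluate_model", "evaluate_models"]


@dataclass
class ModelSpec:
    name: str
    features: tuple


@dataclass
class AucResult:
    model: str
    aucs: np.ndarray
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


_ALL_FEATURES = (
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
)

#: the canonical feature groupings evaluated by the harness
MODEL_SPECS = {
    "CTCF": ModelSpec("CTCF", ("total_ctcf", "inverted_ctcf")),
    "HiC": ModelSpec("HiC", ("hic_contact",)),
    "Enhancer": ModelSpec("Enhancer", ("enh_sharing", "enh_total")),
    "TF": ModelSpec("TF", ("tf_shared", "tfbs_total")),
    "Expression": ModelSpec("Expression", ("diff_expr_level", "diff_coef_var")),
    "GO": ModelSpec("GO", ("go_sharing",)),
    "LD": ModelSpec("LD", ("ld_proxy",)),
    "eQTL sharing": ModelSpec("eQTL sharing", ("eqtl_sharing", "coexp_egenes")),
    "Distance": ModelSpec("Distance", ("tss_distance",)),
    "Combined": ModelSpec("Combined", _ALL_FEATURES),
}


def evaluate_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    reps: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
) -> AucResult:
    """Mean ROC AUC of one feature model over repeated stratified splits."""
    missing = [c for c in spec.features if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    if set(table["label"].unique()) != {0, 1}:
        raise ValueError("table must contain both labels")
    X = table[list(spec.features)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    if all(len(np.unique(X[:, j])) < 2 for j in range(X.shape[1])):
        warnings.warn(
            f"model {spec.name!r} has no varying feature; AUC fixed at 0.5",
            stacklevel=2,
        )
        return AucResult(model=spec.name, aucs=np.full(reps, 0.5), seed=seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    aucs = np.empty(reps)
    for rep in range(reps):
        rng = derive_rng(seed, "classify", spec.name, rep)
        for _attempt in range(10):
            train_idx, test_idx = _stratified_split(pos, neg, train_frac, rng)
            if len(np.unique(y[test_idx])) == 2:
                break
            logger.info("degenerate test split for %s rep %d; resampling", spec.name, rep)
        scaler = StandardScaler().fit(X[train_idx])
        # C=inf -> unregularized fit; features are standardized per fold
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        scores = clf.decision_function(scaler.transform(X[test_idx]))
        aucs[rep] = roc_auc_score(y[test_idx], scores)
    return AucResult(model=spec.name, aucs=aucs, seed=seed)


def _stratified_split(pos, neg, train_frac, rng):
    """80/20 split preserving the class balance of the matched design."""
    tr, te = [], []
    for cls in (pos, neg):
        perm = rng.permutation(cls)
        cut = int(round(train_frac * len(cls)))
        tr.append(perm[:cut])
        te.append(perm[cut:])
    return np.concatenate(tr), np.concatenate(te)


def evaluate_models(
    table: pd.DataFrame,
    specs: dict | None = None,
    reps: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC summary (model, mean_auc, sd_auc) for a dictionary of models."""
    specs = specs or MODEL_SPECS
    rows = []
    for name, spec in specs.items():
        if any(c not in table.columns for c in spec.features):
            continue
        res = evaluate_model(table, spec, reps=reps, train_frac=train_frac, seed=seed)
        rows.append((name, res.mean_auc, float(np.std(res.aucs))))
    return pd.DataFrame(rows, columns=["model", "mean_auc", "sd_auc"])
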