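"""Sorting-performance metrics: ROC/AUC, Wilson intervals, cross-validation,
and confusion tables that account for an "unknown" gating class.

AUC here is the probability that a randomly chosen positive cell outranks a
randomly chosen negative one (ties counting one half) — identical to the
trapezoidal area under the empirical ROC curve. A scorer that ignores the
true class scores 0.5; 1.0 is a perfect sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ROCResult",
    "ConfusionTable",
    "roc_auc",
    "wilson_ci",
    "kfold_cv",
    "confusion_with_unknown",
]

POSITIVE_CLASS = "ev"


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind == "b":
        return labels.astype(int)
    if labels.dtype.kind in "iu" and set(np.unique(labels)) <= {0, 1}:
        return labels.astype(int)
    return (labels == POSITIVE_CLASS).astype(int)


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC curve and its area.

    ``labels`` may be binary {0,1}/bool or class names ('ev' is positive);
    ``scores`` rank cells towards the positive class. Both classes must be
    present.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(y, s)
    return ROCResult(fpr, tpr, thr, float(skmetrics.roc_auc_score(y, s)))


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n.

    The z quantile is computed from the requested confidence (two-sided).
    Bounds are clamped to [0, 1]; (k=0 -> lower bound 0, k=n -> upper 1).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1 (got k={k}, n={n})")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = float(norm.ppf(0.5 + confidence / 2))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    lower = 0.0 if k == 0 else max(0.0, center - half)
    upper = 1.0 if k == n else min(1.0, center + half)
    return (lower, upper)


def kfold_cv(features, labels, model_factory, k: int = 5, seed: int = 0,
             ) -> pd.DataFrame:
    """Stratified k-fold cross-validation of a classifier factory.

    ``model_factory()`` must return an unfitted estimator with fit /
    predict_proba (a fresh one per fold). Returns one row per fold with
    columns ``fold, n_test, auc, accuracy``; folds are a seeded, stratified
    partition covering every cell exactly once.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    if len(X) < k:
        raise ValueError(f"need at least k={k} cells, got {len(X)}")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold needs >= {k} cells per class "
            f"(smallest class has {counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = model_factory()
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        pos_col = list(est.classes_).index(
            POSITIVE_CLASS if POSITIVE_CLASS in est.classes_ else
            est.classes_[-1])
        scores = proba[:, pos_col]
        pred = est.classes_[np.argmax(proba, axis=1)]
        ybin = _as_binary(y[te])
        auc = (roc_auc(scores, y[te]).auc
               if ybin.min() != ybin.max() else np.nan)
        rows.append({"fold": fold, "n_test": len(te), "auc": auc,
                     "accuracy": float(np.mean(pred == y[te]))})
    return pd.DataFrame(rows)


@dataclass
class ConfusionTable:
    """Predicted {apoptotic, ev, unknown} x true {apoptotic, ev} counts.

    ``accuracy`` counts unknown predictions as errors (denominator n);
    ``accuracy_omit_unknown`` removes unknown cells from the denominator
    (NaN when every cell is unknown).
    """

    counts: pd.DataFrame
    accuracy: float
    accuracy_omit_unknown: float
    n: int = field(default=0)


def confusion_with_unknown(predicted, true_labels) -> ConfusionTable:
    pred = np.asarray(
        predicted.labels if hasattr(predicted, "labels") else predicted,
        dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    bad = set(true) - {"apoptotic", "ev"}
    if bad:
        raise ValueError(f"true labels must be apoptotic/ev, got extras {bad}")
    pred_classes = ["apoptotic", "ev", "unknown"]
    true_classes = ["apoptotic", "ev"]
    counts = pd.DataFrame(0, index=pred_classes, columns=true_classes)
    for p, t in zip(pred, true):
        counts.loc[p if p in pred_classes else "unknown", t] += 1
    n = len(true)
    correct = sum(counts.loc[c, c] for c in true_classes)
    n_unknown = int(counts.loc["unknown"].sum())
    acc = correct / n if n else np.nan
    acc_omit = correct / (n - n_unknown) if n > n_unknown else np.nan
    return ConfusionTable(counts, float(acc), float(acc_omit), n)
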