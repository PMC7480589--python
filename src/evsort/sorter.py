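"""Random-forest cell sorting, channel-wise importance, and manual gating.

The sorter is a random forest (1000 trees, sqrt features per split) trained
on either the autoencoder's 256-d features (CAE-RF) or the classical feature
schema (CP-RF). The forest always assigns every cell to apoptotic or ev; the
manual-gating baseline, in contrast, may leave cells "unknown" when they
fall in neither gate.

The module also provides the package's statsmodels-style front door:
``CellSorter`` (a model bound to training data) whose ``fit()`` returns a
``CellSorterResults`` carrying the fitted forest, per-class probabilities on
held-out data, Gini importances grouped by channel, and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluate import POSITIVE_CLASS, roc_auc, wilson_ci, confusion_with_unknown
from .io import PopulationFile

__all__ = [
    "RFConfig",
    "SortResult",
    "GateSpec",
    "train_rf",
    "predict_labels",
    "channel_importance",
    "gate_classify",
    "CellSorter",
    "CellSorterResults",
]

CLASSES = ("apoptotic", "ev")


@dataclass
class RFConfig:
    """Forest hyperparameters (defaults follow the published setting)."""

    n_trees: int = 1000
    max_features: str = "sqrt"
    seed: int = 0
    class_weight: str | None = None  # imbalance handling off by default

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class SortResult:
    """Per-cell class assignment with probabilities.

    ``labels`` take values in {apoptotic, ev, unknown}; forest-based methods
    never emit unknown. ``proba`` columns are (apoptotic, ev) and sum to 1
    where defined. ``overlap_count`` is a gating diagnostic: cells that fell
    inside both gates (resolved to apoptotic by documented priority).
    """

    object_ids: np.ndarray
    labels: np.ndarray
    proba: pd.DataFrame
    method: str
    overlap_count: int = 0

    def __post_init__(self) -> None:
        self.object_ids = np.asarray(self.object_ids)
        self.labels = np.asarray(self.labels, dtype=object)

    def counts(self) -> dict:
        vals, cnt = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals, cnt.tolist()))

    def to_population_files(self, prefix: str = "sorted",
                            ) -> dict[str, PopulationFile]:
        """Split object ids into per-class populations (a partition)."""
        pops = {}
        present = ["apoptotic", "ev"]
        if (self.labels == "unknown").any():
            present.append("unknown")
        for cls in present:
            ids = [int(i) for i in self.object_ids[self.labels == cls]]
            pops[cls] = PopulationFile(f"{prefix}_{cls}", ids)
        return pops


def train_rf(features, labels, config: RFConfig | None = None,
             ) -> RandomForestClassifier:
    """Fit the sorting forest; deterministic given the seed.

    Accepts heavily class-imbalanced input (the annotated training corpus
    is ~66:1); requires at least two cells of each class.
    """
    config = config or RFConfig()
    X = np.asarray(features)
    y = np.asarray(labels, dtype=object).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least two cells per class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=config.max_features,
        random_state=config.seed, class_weight=config.class_weight,
        n_jobs=1)
    forest.fit(X, y)
    return forest


def predict_labels(forest: RandomForestClassifier, features,
                   object_ids=None, threshold: float = 0.5,
                   method: str = "cae_rf") -> SortResult:
    """Label every cell (no unknowns): ev iff P(ev) > threshold.

    The tie at exactly P(ev) == threshold goes to apoptotic (documented
    tie-break). The result partitions the input ids into the two classes.
    """
    X = np.asarray(features)
    if X.shape[1] != forest.n_features_in_:
        raise ValueError(
            f"feature schema mismatch: forest expects "
            f"{forest.n_features_in_} features, got {X.shape[1]}")
    proba = forest.predict_proba(X)
    cols = list(forest.classes_)
    p_ev = proba[:, cols.index(POSITIVE_CLASS)] if POSITIVE_CLASS in cols \
        else np.zeros(len(X))
    labels = np.where(p_ev > threshold, "ev", "apoptotic").astype(object)
    if object_ids is None:
        object_ids = np.arange(len(X))
    frame = pd.DataFrame({"apoptotic": 1.0 - p_ev, "ev": p_ev})
    return SortResult(np.asarray(object_ids), labels, frame, method)


def channel_importance(forest: RandomForestClassifier,
                       feature_channel_map: Sequence[str]) -> pd.DataFrame:
    """Gini importances grouped by the channel that produced each feature.

    Returns one row per feature (columns: feature index, channel,
    importance); group medians are attached as ``frame.attrs['median']``.
    Raises if the map does not cover the forest's features.
    """
    chan = np.asarray(feature_channel_map)
    imp = forest.feature_importances_
    if len(chan) != len(imp):
        raise ValueError(
            f"feature-channel map covers {len(chan)} features but the "
            f"forest has {len(imp)}")
    frame = pd.DataFrame({"feature": np.arange(len(imp)),
                          "channel": chan, "importance": imp})
    frame.attrs["median"] = frame.groupby("channel")["importance"].median()
    return frame


@dataclass
class GateSpec:
    """Axis-aligned rectangular gates over two named features.

    Each gate maps a class to {feature: (low, high)} bounds; containment is
    closed on the lower bound and open on the upper ([low, high)). Cells in
    neither gate are unknown; cells in both resolve to apoptotic (documented
    priority) and increment the overlap diagnostic.
    """

    gates: Mapping[str, Mapping[str, tuple]]

    def __post_init__(self) -> None:
        for cls in self.gates:
            if cls not in CLASSES:
                raise ValueError(f"gate class must be in {CLASSES}: {cls!r}")

    def contains(self, cls: str, row: Mapping[str, float]) -> bool:
        for feat, (lo, hi) in self.gates[cls].items():
            if feat not in row:
                raise KeyError(f"gate references missing feature {feat!r}")
            if not (lo <= row[feat] < hi):
                return False
        return True


def gate_classify(features: pd.DataFrame, spec: GateSpec,
                  object_ids=None) -> SortResult:
    """Manual-gating baseline with an explicit unknown class."""
    if not isinstance(features, pd.DataFrame):
        raise TypeError("gate_classify expects a named-feature DataFrame")
    missing = {f for g in spec.gates.values() for f in g} - set(features.columns)
    if missing:
        raise KeyError(f"gate references missing feature(s) {sorted(missing)}")
    labels = np.empty(len(features), dtype=object)
    overlap = 0
    for i, (_, row) in enumerate(features.iterrows()):
        in_ap = "apoptotic" in spec.gates and spec.contains("apoptotic", row)
        in_ev = "ev" in spec.gates and spec.contains("ev", row)
        if in_ap and in_ev:
            labels[i] = "apoptotic"  # documented priority
            overlap += 1
        elif in_ap:
            labels[i] = "apoptotic"
        elif in_ev:
            labels[i] = "ev"
        else:
            labels[i] = "unknown"
    if object_ids is None:
        object_ids = np.arange(len(features))
    nan = np.full(len(features), np.nan)
    proba = pd.DataFrame({"apoptotic": nan, "ev": nan})
    return SortResult(np.asarray(object_ids), labels, proba, "gating",
                      overlap_count=overlap)


# ---------------------------------------------------------------------------
# model / results front door
# ---------------------------------------------------------------------------

class CellSorter:
    """A cell-sorting model bound to annotated training features.

    Parameters
    ----------
    features : (n, p) array
        Per-cell feature vectors (CAE or classical).
    labels : sequence of {'apoptotic', 'ev'}
    feature_channel_map : optional sequence
        Channel tag per feature; enables channel-wise importance.
    config : RFConfig
    method : str
        Name recorded on predictions ('cae_rf' or 'cp_rf').
    """

    def __init__(self, features, labels, feature_channel_map=None,
                 config: RFConfig | None = None, method: str = "cae_rf"):
        self.features = np.asarray(features)
        self.labels = np.asarray(labels, dtype=object)
        if len(self.features) != len(self.labels):
            raise ValueError("features/labels length mismatch")
        self.feature_channel_map = (
            None if feature_channel_map is None
            else np.asarray(feature_channel_map))
        self.config = config or RFConfig()
        self.method = method

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str = "label",
                       **kwargs) -> "CellSorter":
        y = frame[label_column].to_numpy()
        X = frame.drop(columns=[label_column])
        return cls(X.to_numpy(), y, **kwargs)

    def fit(self) -> "CellSorterResults":
        forest = train_rf(self.features, self.labels, self.config)
        return CellSorterResults(self, forest)


class CellSorterResults:
    """Fitted sorter: predictions, importances, accuracy with Wilson CIs."""

    def __init__(self, model: CellSorter, forest: RandomForestClassifier):
        self.model = model
        self.forest = forest

    def predict(self, features, object_ids=None,
                threshold: float = 0.5) -> SortResult:
        return predict_labels(self.forest, features, object_ids,
                              threshold, self.model.method)

    def score(self, features, true_labels) -> dict:
        """AUC, accuracy and its 95% Wilson CI on an annotated set."""
        result = self.predict(features)
        auc = roc_auc(result.proba["ev"].to_numpy(), true_labels).auc
        correct = int(np.sum(result.labels == np.asarray(true_labels,
                                                         dtype=object)))
        n = len(result.labels)
        lo, hi = wilson_ci(correct, n)
        table = confusion_with_unknown(result, true_labels)
        return {"auc": auc, "accuracy": correct / n,
                "accuracy_ci": (lo, hi), "n": n, "confusion": table}

    def channel_importance(self) -> pd.DataFrame:
        if self.model.feature_channel_map is None:
            raise ValueError("model was built without a feature-channel map")
        return channel_importance(self.forest, self.model.feature_channel_map)

    def summary(self) -> str:
        classes, counts = np.unique(self.model.labels.astype(str),
                                    return_counts=True)
        lines = [
            "Cell sorter (random forest on image features)",
            "=" * 46,
            f"method:           {self.model.method}",
            f"training cells:   {len(self.model.labels)} "
            f"({', '.join(f'{c}={n}' for c, n in zip(classes, counts))})",
            f"features:         {self.model.features.shape[1]}",
            f"trees:            {self.config_summary()}",
        ]
        if self.model.feature_channel_map is not None:
            med = self.channel_importance().attrs["median"]
            for chan, val in med.items():
                lines.append(f"median Gini importance [{chan}]: {val:.5f}")
        return "\n".join(lines)

    def config_summary(self) -> str:
        c = self.model.config
        return f"{c.n_trees} (max_features={c.max_features}, seed={c.seed})"

    def plot_roc(self, features, true_labels, ax=None):
        """ROC curve on an annotated set (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        result = self.predict(features)
        roc = roc_auc(result.proba["ev"].to_numpy(), true_labels)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(roc.fpr, roc.tpr, label=f"{self.model.method} "
                                        f"(AUC={roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend()
        return ax
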