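"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, stratified
cross-validation and perturbation-based feature importance.

AUC is computed by trapezoidal integration of the ROC curve over all
distinct score thresholds, which coincides with the Mann-Whitney
concordance probability (ties counted one half). Perturbation importance
zeroes one feature column at a time on the normalised scale — i.e. pins it
at its observed training minimum — and records the accuracy drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anfis
from .errors import StratificationError, UndefinedMetricError

#: Importance tiers by accuracy-drop cutoffs (descending).
IMPORTANCE_TIERS = (
    ("Dominant", 0.005),
    ("High", 0.0025),
    ("Moderate", 0.001),
    ("Low", -math.inf),
)


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise UndefinedMetricError("confusion counts must be non-negative")
        if self.total == 0:
            raise UndefinedMetricError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


@dataclass
class MetricSet:
    """Binary-classification metrics; a metric with a zero denominator is
    stored as None (undefined) rather than silently coerced to 0."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    false_negative_rate: float | None = None
    false_positive_rate: float | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "false_negative_rate": self.false_negative_rate,
            "false_positive_rate": self.false_positive_rate,
            "auc": self.auc,
        }


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a probability threshold.

    A case is predicted positive iff its probability strictly exceeds the
    threshold, so ties at exactly 0.5 count as negative.
    """
    labels = np.asarray(labels).astype(int).ravel()
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    if labels.size == 0:
        raise UndefinedMetricError("cannot evaluate an empty label set")
    if labels.shape != probabilities.shape:
        raise UndefinedMetricError("labels and probabilities differ in length")
    predicted = probabilities > threshold
    positive = labels == 1
    return ConfusionCounts(
        tn=int(np.sum(~predicted & ~positive)),
        fp=int(np.sum(predicted & ~positive)),
        fn=int(np.sum(~predicted & positive)),
        tp=int(np.sum(predicted & positive)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """Derive the standard metric set from confusion counts (AUC unset)."""
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    f1 = None
    if sensitivity is not None and precision is not None and sensitivity + precision > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        accuracy=_ratio(c.tn + c.tp, c.total),
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=precision,
        f1=f1,
        false_negative_rate=_ratio(c.fn, c.tp + c.fn),
        false_positive_rate=_ratio(c.fp, c.tn + c.fp),
    )


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Thresholds sweep all distinct scores; the result equals the probability
    that a random positive outscores a random negative, with ties counted
    half.
    """
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # cumulative TP/FP after each distinct-threshold block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

_CV_METRICS = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "auc",
)


def summarize_cv_metric(values) -> dict[str, float]:
    """Mean, sample SD and normal-approximation 95% CI over fold values."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    half = 1.96 * sd / math.sqrt(len(values))
    return {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = {}
        for name in _CV_METRICS:
            values = [getattr(m, name) for m in self.fold_metrics]
            if any(v is None for v in values):
                continue
            rows[name] = summarize_cv_metric(values)
        self.summary = pd.DataFrame.from_dict(rows, orient="index")

    @property
    def n_folds(self) -> int:
        return len(self.fold_metrics)

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.fold_metrics]).rename_axis(
            "fold"
        )


def cross_validate(
    features,
    labels,
    k: int = 5,
    config: anfis.TrainingConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the ANFIS classifier.

    Each fold's model is trained from scratch on the remaining folds and
    evaluated on the held-out fold. Fold assignment uses seeded stratified
    shuffling; fold class counts stay within one of proportionality.
    """
    from sklearn.model_selection import StratifiedKFold

    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(labels).astype(int).ravel()
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < k:
        raise StratificationError(f"each class needs at least {k} members")
    config = config or anfis.TrainingConfig()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        classifier = anfis.ANFISClassifier(
            y[train_idx], X[train_idx], feature_names=names
        )
        results = classifier.fit(config, seed=config.seed + fold)
        metrics = results.evaluate(X[test_idx], y[test_idx])
        fold_metrics.append(metrics)
    return CVResult(fold_metrics)


# ---------------------------------------------------------------------------
# perturbation importance
# ---------------------------------------------------------------------------

def tier_for(contribution: float) -> str:
    for label, cutoff in IMPORTANCE_TIERS:
        if contribution >= cutoff:
            return label
    return "Low"


def perturbation_importance(
    results: "anfis.ANFISResults | anfis.ANFISModel",
    features,
    labels,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Zero-ablation feature importance.

    For each feature the column is set to 0 on the normalised scale (the
    feature's observed minimum), accuracy is recomputed, and the importance
    is the baseline-minus-perturbed accuracy difference. Returns a table
    indexed by feature name with columns ``contribution``, ``rank`` and
    ``tier``, sorted by rank.
    """
    model = anfis.require_trained(results)
    if isinstance(features, pd.DataFrame):
        X = features[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if len(X) == 0:
        raise UndefinedMetricError("cannot compute importance on an empty set")

    def accuracy(matrix: np.ndarray) -> float:
        probs = anfis.predict_proba(model, matrix)
        return float(np.mean((probs > threshold) == y))

    baseline = accuracy(X)
    contributions = {}
    for j, name in enumerate(model.feature_names):
        perturbed = X.copy()
        perturbed[:, j] = 0.0
        contributions[name] = baseline - accuracy(perturbed)
    table = pd.DataFrame({"contribution": pd.Series(contributions)})
    table = table.sort_values("contribution", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    table["tier"] = [tier_for(v) for v in table["contribution"]]
    return table
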