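"""Engineered model inputs for the neuro-fuzzy screening classifier.

Eleven features are constructed from each child record: the four raw domain
scores, four age-adjusted ratios (score / chronological age), two
cross-domain ratios (cognitive/(social+1) and motor/(behavioral+1), the +1
guarding the denominator), and a weighted composite risk score built from
inverted (100 - x) domain scores with a multiplicative family-history
factor. Ratios and the risk score are computed on the raw 0-100 scale;
the full 11-column matrix is then min-max normalised to [0, 1].

A mutual-information screen (equal-width binning) flags features whose MI
with the diagnosis exceeds a small threshold; the model consumes all 11
features by default regardless, with the screen serving as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing
from .errors import InvalidParameterError, SchemaError, UndefinedMetricError

#: Fixed, versioned feature order. Perturbation-importance indices refer to it.
FEATURE_ORDER = (
    "cognitive",
    "behavioral",
    "motor",
    "social",
    "cognitive_age_ratio",
    "behavioral_age_ratio",
    "motor_age_ratio",
    "social_age_ratio",
    "cognitive_social_ratio",
    "motor_behavioral_ratio",
    "composite_risk",
)

_DOMAIN_TO_COLUMN = {
    "cognitive": "cognitive_score",
    "behavioral": "behavioral_score",
    "motor": "motor_skills",
    "social": "social_interaction",
}


@dataclass(frozen=True)
class CompositeRiskWeights:
    """Domain weights and family-history multiplier for the composite risk.

    Cognitive and social carry weight 0.3 each, behavioral and motor 0.2
    each (they must sum to 1); a positive family history scales the base
    risk multiplicatively.
    """

    w_cognitive: float = 0.3
    w_behavioral: float = 0.2
    w_motor: float = 0.2
    w_social: float = 0.3
    fh_multiplier_positive: float = 1.25
    fh_multiplier_negative: float = 1.0

    def __post_init__(self) -> None:
        total = self.w_cognitive + self.w_behavioral + self.w_motor + self.w_social
        if not np.isclose(total, 1.0):
            raise InvalidParameterError(f"domain weights must sum to 1, got {total}")
        if self.fh_multiplier_positive < 1.0:
            raise InvalidParameterError("fh_multiplier_positive must be >= 1")


DEFAULT_WEIGHTS = CompositeRiskWeights()


def age_adjusted_ratio(score, age):
    """Domain score divided by chronological age (years, >= 1)."""
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age < 1):
        raise InvalidParameterError("age must be >= 1 year")
    return score / age


def cognitive_social_ratio(cognitive, social):
    """Cognitive score over (social score + 1); finite for all scores >= 0."""
    cognitive = np.asarray(cognitive, dtype=float)
    social = np.asarray(social, dtype=float)
    if np.any(cognitive < 0) or np.any(social < 0):
        raise InvalidParameterError("scores must be non-negative")
    return cognitive / (social + 1.0)


def motor_behavioral_ratio(motor, behavioral):
    """Motor score over (behavioral score + 1); finite for all scores >= 0."""
    motor = np.asarray(motor, dtype=float)
    behavioral = np.asarray(behavioral, dtype=float)
    if np.any(motor < 0) or np.any(behavioral < 0):
        raise InvalidParameterError("scores must be non-negative")
    return motor / (behavioral + 1.0)


def composite_risk(
    cognitive,
    behavioral,
    motor,
    social,
    family_history,
    weights: CompositeRiskWeights = DEFAULT_WEIGHTS,
):
    """Weighted sum of inverted (100 - x) domain scores, scaled by the
    family-history multiplier. Higher values mean greater developmental risk;
    with multiplier 1 the range is exactly [0, 100]."""
    arrays = [np.asarray(a, dtype=float) for a in (cognitive, behavioral, motor, social)]
    for a in arrays:
        if np.any((a < 0) | (a > 100)):
            raise InvalidParameterError("domain scores must lie in [0, 100]")
    cognitive, behavioral, motor, social = arrays
    base = (
        weights.w_cognitive * (100.0 - cognitive)
        + weights.w_behavioral * (100.0 - behavioral)
        + weights.w_motor * (100.0 - motor)
        + weights.w_social * (100.0 - social)
    )
    multiplier = np.where(
        np.asarray(family_history).astype(bool),
        weights.fh_multiplier_positive,
        weights.fh_multiplier_negative,
    )
    return base * multiplier


def build_raw_features(
    records: pd.DataFrame, weights: CompositeRiskWeights = DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Compute the 11 engineered features on the raw 0-100 score scale."""
    required = set(_DOMAIN_TO_COLUMN.values()) | {"age", "family_history"}
    missing = required - set(records.columns)
    if missing:
        raise SchemaError(f"records missing columns: {sorted(missing)}")
    if records[sorted(required)].isna().any().any():
        raise SchemaError("records contain missing values; run preprocessing first")
    out = pd.DataFrame(index=records.index)
    for feature, column in _DOMAIN_TO_COLUMN.items():
        out[feature] = records[column].astype(float)
        out[f"{feature}_age_ratio"] = age_adjusted_ratio(
            records[column], records["age"]
        )
    out["cognitive_social_ratio"] = cognitive_social_ratio(
        records["cognitive_score"], records["social_interaction"]
    )
    out["motor_behavioral_ratio"] = motor_behavioral_ratio(
        records["motor_skills"], records["behavioral_score"]
    )
    out["composite_risk"] = composite_risk(
        records["cognitive_score"],
        records["behavioral_score"],
        records["motor_skills"],
        records["social_interaction"],
        records["family_history"],
        weights,
    )
    return out[list(FEATURE_ORDER)]


def build_feature_matrix(
    records: pd.DataFrame,
    scaler: preprocessing.ScalerParams | None = None,
    weights: CompositeRiskWeights = DEFAULT_WEIGHTS,
) -> tuple[pd.DataFrame, preprocessing.ScalerParams]:
    """Engineered features, min-max normalised to [0, 1].

    When ``scaler`` is None a new one is fitted on these records (training
    path); otherwise the given parameters are applied with clamping (test
    path — never fit the scaler on evaluation data).
    """
    raw = build_raw_features(records, weights)
    if scaler is None:
        scaler = preprocessing.fit_scaler(raw, list(FEATURE_ORDER))
    return preprocessing.transform(raw, scaler), scaler


def mutual_information_screen(
    features: pd.DataFrame,
    labels,
    threshold: float = 0.01,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Histogram mutual information of each feature with the binary label.

    Each continuous feature is discretised into ``n_bins`` equal-width bins
    over its observed range and MI (natural log) with the label is computed
    from the joint histogram. Returns a table with columns ``mi`` and
    ``retained`` (MI > threshold) indexed by feature name. Constant
    features score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("mutual information needs both label classes")
    y = (labels == labels.max()).astype(int)
    rows = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if not lo < hi:
            rows[name] = 0.0
            continue
        joint, _, _ = np.histogram2d(x, y, bins=[n_bins, 2], range=[[lo, hi], [-0.5, 1.5]])
        joint /= joint.sum()
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nonzero = joint > 0
        rows[name] = float(
            np.sum(joint[nonzero] * np.log(joint[nonzero] / (px @ py)[nonzero]))
        )
    table = pd.DataFrame({"mi": pd.Series(rows)})
    table["retained"] = table["mi"] > threshold
    return table
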