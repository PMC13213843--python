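"""Interpretable clinical reporting for screening predictions.

A prediction is turned into clinician-facing output: the hard
classification, a confidence score (distance of the probability from the
0.5 decision threshold, normalised to [0, 1]) stratified into Low / Medium
/ High tiers, linguistic membership labels for each assessment domain, the
top contributing features for this particular child (per-case
zero-ablation), and a templated recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anfis, features
from .errors import InvalidParameterError, ModelStateError, SchemaError

#: Tier cutoffs: Low iff <= 0.5, Medium in (0.5, 0.8], High > 0.8.
TIER_CUTOFFS = ((0.5, "Low"), (0.8, "Medium"))

#: Membership-gap below which the top two linguistic labels are blended.
BLEND_GAP = 0.15

NEGATIVE, POSITIVE = "no diagnosis", "diagnosis"

RECOMMENDATIONS = {
    (NEGATIVE, "High"): "Continue routine monitoring",
    (NEGATIVE, "Medium"): (
        "Continue routine monitoring; re-assess at the next scheduled visit"
    ),
    (NEGATIVE, "Low"): (
        "Refer for clinical review; prediction confidence is low"
    ),
    (POSITIVE, "High"): "Refer for comprehensive diagnostic evaluation",
    (POSITIVE, "Medium"): (
        "Refer for comprehensive diagnostic evaluation; prioritise follow-up"
    ),
    (POSITIVE, "Low"): (
        "Refer for clinical review and repeat screening; prediction confidence is low"
    ),
}

_DOMAIN_FEATURES = {
    "cognitive_score": "cognitive",
    "behavioral_score": "behavioral",
    "motor_skills": "motor",
    "social_interaction": "social",
}


def confidence(p: float) -> float:
    """Distance of a probability from the 0.5 threshold, scaled to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"probability {p} outside [0, 1]")
    return abs(p - 0.5) / 0.5


def confidence_tier(conf: float) -> str:
    """Map a confidence value to Low (<= 0.5), Medium (0.5, 0.8], High (> 0.8)."""
    if not 0.0 <= conf <= 1.0:
        raise InvalidParameterError(f"confidence {conf} outside [0, 1]")
    for cutoff, label in TIER_CUTOFFS:
        if conf <= cutoff:
            return label
    return "High"


def mf_label(
    raw_score: float,
    mfs: tuple[anfis.MembershipFunction, ...],
    value_range: tuple[float, float],
) -> str:
    """Linguistic label of a raw score under a fitted membership triple.

    The score is min-max normalised with the fitted range (clamped), the
    three memberships are evaluated, and the argmax label returned; when
    the top two memberships differ by less than ``BLEND_GAP`` the two
    labels are blended in ascending order, e.g. ``"Medium–High"``.
    """
    if mfs is None or len(mfs) != len(anfis.MF_LABELS):
        raise ModelStateError("a trained membership triple is required")
    lo, hi = value_range
    x = min(max((raw_score - lo) / (hi - lo), 0.0), 1.0)
    mu = np.array([anfis.gaussian_membership(x, mf) for mf in mfs])
    order = np.argsort(-mu, kind="stable")
    top, second = order[0], order[1]
    if mu[top] - mu[second] < BLEND_GAP:
        first, last = sorted((top, second))
        return f"{anfis.MF_LABELS[first]}–{anfis.MF_LABELS[last]}"
    return anfis.MF_LABELS[top]


@dataclass
class ClinicalReport:
    """Structured, interpretable output for one child."""

    child_id: str
    prediction: str
    probability: float
    confidence: float
    confidence_tier: str
    domain_labels: dict[str, str]
    feature_values: dict[str, float]
    top_features: list[tuple[str, float]]
    recommendation: str

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "prediction": self.prediction,
            "probability": self.probability,
            "confidence": self.confidence,
            "confidence_tier": self.confidence_tier,
            "domain_labels": dict(self.domain_labels),
            "feature_values": dict(self.feature_values),
            "top_features": [list(pair) for pair in self.top_features],
            "recommendation": self.recommendation,
        }

    def to_text(self) -> str:
        lines = [
            f"Clinical screening report — child {self.child_id}",
            "=" * 56,
            f"Prediction       : {self.prediction}",
            f"Probability      : {self.probability:.3f}",
            f"Confidence       : {self.confidence:.1%} ({self.confidence_tier})",
            "",
            "Domain assessment (membership classification):",
        ]
        for domain, label in self.domain_labels.items():
            value = self.feature_values[_DOMAIN_FEATURES[domain]]
            lines.append(f"  {domain:<20} {value:>7.2f}  {label}")
        lines += [
            "",
            f"  cognitive_social_ratio {self.feature_values['cognitive_social_ratio']:.2f}"
            f"   composite_risk {self.feature_values['composite_risk']:.2f}",
            "",
            "Primary contributing features (per-case zero-ablation, |d probability|):",
        ]
        for name, delta in self.top_features:
            lines.append(f"  {name:<24} {delta:.4f}")
        lines += ["", f"Recommendation: {self.recommendation}"]
        return "\n".join(lines)


def generate_report(
    record,
    results: anfis.ANFISResults,
    weights: features.CompositeRiskWeights = features.DEFAULT_WEIGHTS,
    n_top: int = 3,
) -> ClinicalReport:
    """Build the full clinical report for one raw child record.

    ``record`` is a mapping/Series with the raw assessment columns;
    ``results`` must carry both the trained model and the fitted feature
    scaler. Per-case feature contributions are measured by zeroing each
    normalised feature of this one record and ranking |delta probability|.
    """
    model = anfis.require_trained(results)
    if results.scaler is None:
        raise ModelStateError("results must carry fitted scaler parameters")
    if isinstance(record, pd.Series):
        record = record.to_dict()
    required = set(_DOMAIN_FEATURES) | {"age", "family_history"}
    missing = required - set(record)
    if missing:
        raise SchemaError(f"record is missing fields: {sorted(missing)}")
    frame = pd.DataFrame([record])
    raw = features.build_raw_features(frame, weights)
    normalized, _ = features.build_feature_matrix(frame, results.scaler, weights)
    x = normalized.to_numpy(dtype=float)[0]

    p = anfis.forward(x, model)
    prediction = POSITIVE if p > 0.5 else NEGATIVE
    conf = confidence(p)
    tier = confidence_tier(conf)

    domain_labels = {}
    for column, feature in _DOMAIN_FEATURES.items():
        idx = model.feature_names.index(feature)
        domain_labels[column] = mf_label(
            float(record[column]),
            model.membership_bank(idx),
            (results.scaler.minima[feature], results.scaler.maxima[feature]),
        )

    deltas = []
    for j, name in enumerate(model.feature_names):
        ablated = x.copy()
        ablated[j] = 0.0
        deltas.append((name, abs(anfis.forward(ablated, model) - p)))
    deltas.sort(key=lambda pair: -pair[1])

    return ClinicalReport(
        child_id=str(record.get("child_id", "?")),
        prediction=prediction,
        probability=float(p),
        confidence=conf,
        confidence_tier=tier,
        domain_labels=domain_labels,
        feature_values={k: float(v) for k, v in raw.iloc[0].items()},
        top_features=deltas[:n_top],
        recommendation=RECOMMENDATIONS[(prediction, tier)],
    )
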