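"""Deterministic data preparation: encoding, missing-data policy, min-max
normalisation and stratified train/test splitting.

All steps are fit on training data only where a fit is involved; the scaler
clamps out-of-range values seen at transform time rather than extrapolating
outside [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EncodingError,
    SchemaError,
    StratificationError,
    UnimputableColumnError,
    ZeroRangeError,
)

SEX_CODES = {"male": 0, "female": 1}

#: Columns subject to the row-exclusion rule for excess missingness.
DEFAULT_KEY_COLUMNS = (
    "cognitive_score",
    "behavioral_score",
    "motor_skills",
    "social_interaction",
    "age",
    "family_history",
)


def encode_sex(
    records: pd.DataFrame, column: str = "sex", case_fold: bool = False
) -> pd.DataFrame:
    """Encode the sex column as male -> 0, female -> 1.

    The mapping is case-sensitive by default; pass ``case_fold=True`` to
    accept e.g. "Male". Unrecognised labels raise :class:`EncodingError`
    naming the offending value.
    """
    if column not in records.columns:
        raise SchemaError(f"column {column!r} not present")
    values = records[column]
    if case_fold:
        values = values.str.lower()
    unknown = set(values.unique()) - set(SEX_CODES)
    if unknown:
        raise EncodingError(f"unrecognised sex label(s): {sorted(map(str, unknown))}")
    out = records.copy()
    out[column] = values.map(SEX_CODES).astype(int)
    return out


def decode_sex(records: pd.DataFrame, column: str = "sex") -> pd.DataFrame:
    """Invert :func:`encode_sex` (0 -> male, 1 -> female)."""
    inverse = {v: k for k, v in SEX_CODES.items()}
    out = records.copy()
    out[column] = records[column].map(inverse)
    return out


@dataclass
class MissingDataLog:
    """Counts of rows dropped and cells imputed by the missing-data policy."""

    rows_dropped: int = 0
    imputed_cells: dict[str, int] = field(default_factory=dict)
    column_means: dict[str, float] = field(default_factory=dict)

    @property
    def total_imputed(self) -> int:
        return sum(self.imputed_cells.values())


def apply_missing_policy(
    records: pd.DataFrame,
    key_columns: tuple[str, ...] = DEFAULT_KEY_COLUMNS,
    drop_threshold: float = 0.10,
) -> tuple[pd.DataFrame, MissingDataLog]:
    """Drop rows with excess key-column missingness, then mean-impute.

    A row is excluded when the fraction of its missing cells among
    ``key_columns`` exceeds ``drop_threshold``; remaining missing cells (in
    any numeric column) are replaced with the column mean computed over the
    kept rows. Idempotent: the output passes through unchanged.
    """
    missing_keys = set(key_columns) - set(records.columns)
    if missing_keys:
        raise SchemaError(f"key columns not in table: {sorted(missing_keys)}")
    frac_missing = records[list(key_columns)].isna().mean(axis=1)
    kept = records.loc[frac_missing <= drop_threshold].copy()
    log = MissingDataLog(rows_dropped=int((frac_missing > drop_threshold).sum()))
    for column in kept.columns:
        if not pd.api.types.is_numeric_dtype(kept[column]):
            continue
        n_missing = int(kept[column].isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(kept):
            raise UnimputableColumnError(f"column {column!r} is entirely missing")
        mean = float(kept[column].mean())
        kept[column] = kept[column].fillna(mean)
        log.imputed_cells[column] = n_missing
        log.column_means[column] = mean
    return kept, log


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature observed minima and maxima, fitted on training data only."""

    minima: dict[str, float]
    maxima: dict[str, float]

    @property
    def columns(self) -> list[str]:
        return list(self.minima)

    def to_dict(self) -> dict:
        return {"minima": dict(self.minima), "maxima": dict(self.maxima)}

    @classmethod
    def from_dict(cls, raw: dict) -> "ScalerParams":
        return cls(minima=dict(raw["minima"]), maxima=dict(raw["maxima"]))


def fit_scaler(train: pd.DataFrame, columns: list[str] | None = None) -> ScalerParams:
    """Record per-column min/max over the training partition.

    Raises :class:`ZeroRangeError` for a constant column, whose min-max
    image would be undefined.
    """
    columns = list(columns) if columns is not None else list(train.columns)
    minima, maxima = {}, {}
    for column in columns:
        if column not in train.columns:
            raise SchemaError(f"column {column!r} not in training table")
        lo = float(train[column].min())
        hi = float(train[column].max())
        if not lo < hi:
            raise ZeroRangeError(f"column {column!r} is constant (value {lo})")
        minima[column], maxima[column] = lo, hi
    return ScalerParams(minima=minima, maxima=maxima)


def transform(records: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Map each fitted column to (x - min) / (max - min), clamped to [0, 1].

    Clamping means values outside the training range (possible on a test
    partition) map to the boundary rather than outside the unit interval.
    """
    out = records.copy()
    for column in params.columns:
        if column not in out.columns:
            raise SchemaError(f"column {column!r} not in table")
        lo, hi = params.minima[column], params.maxima[column]
        out[column] = ((out[column] - lo) / (hi - lo)).clip(0.0, 1.0)
    return out


def inverse_transform(records: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Map normalised columns back to the original scale (no clamping)."""
    out = records.copy()
    for column in params.columns:
        lo, hi = params.minima[column], params.maxima[column]
        out[column] = out[column] * (hi - lo) + lo
    return out


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    stratify_on: str = "diagnosis"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise StratificationError("test_fraction must be in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    records: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified train/test split with exact per-class rounding.

    The per-class test count is ``round(test_fraction * class_size)``
    (half away from zero); if per-class rounding perturbs the overall test
    count away from ``round(test_fraction * n)``, the majority class is
    adjusted by at most one record to reconcile the total.
    """
    spec = spec or SplitSpec()
    if spec.stratify_on not in records.columns:
        raise SchemaError(f"stratification column {spec.stratify_on!r} not present")
    labels = records[spec.stratify_on]
    class_sizes = labels.value_counts()
    if len(class_sizes) < 2 or class_sizes.min() < 2:
        raise StratificationError(
            "each class needs at least 2 members to stratify; "
            f"got {class_sizes.to_dict()}"
        )
    test_counts = {
        cls: _round_half_away(spec.test_fraction * n)
        for cls, n in class_sizes.items()
    }
    target_total = _round_half_away(spec.test_fraction * len(records))
    drift = sum(test_counts.values()) - target_total
    if drift != 0:
        majority = class_sizes.idxmax()
        test_counts[majority] -= int(np.sign(drift)) * min(abs(drift), 1)
    for cls, count in test_counts.items():
        if count < 1 or count >= class_sizes[cls]:
            raise StratificationError(
                f"class {cls!r} too small for test_fraction={spec.test_fraction}"
            )
    rng = np.random.default_rng(spec.seed)
    test_idx: list[np.ndarray] = []
    for cls, count in test_counts.items():
        members = records.index[labels == cls].to_numpy()
        test_idx.append(rng.permutation(members)[:count])
    test_index = np.concatenate(test_idx)
    test_mask = records.index.isin(test_index)
    return records.loc[~test_mask].copy(), records.loc[test_mask].copy()
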