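"""End-to-end glue: cohort table -> cleaned splits -> features -> fitted model.

Thin composition of the preprocessing, feature-engineering and ANFIS
modules so that scripts, tests and the CLI share one code path. The
feature scaler is always fitted on the training partition only and carried
on the returned results object for later raw-score inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anfis, features, preprocessing
from .errors import StratificationError


@dataclass
class PipelineData:
    """Prepared partitions of one cohort."""

    train: pd.DataFrame
    test: pd.DataFrame
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    scaler: preprocessing.ScalerParams


def prepare(
    cohort: pd.DataFrame,
    split: preprocessing.SplitSpec | None = None,
    weights: features.CompositeRiskWeights = features.DEFAULT_WEIGHTS,
) -> PipelineData:
    """Clean, encode, split and featurise a raw cohort table."""
    cleaned, _ = preprocessing.apply_missing_policy(cohort)
    if cleaned["sex"].dtype == object:
        cleaned = preprocessing.encode_sex(cleaned)
    train, test = preprocessing.stratified_split(cleaned, split)
    X_train, scaler = features.build_feature_matrix(train, None, weights)
    X_test, _ = features.build_feature_matrix(test, scaler, weights)
    return PipelineData(
        train=train,
        test=test,
        X_train=X_train,
        y_train=train["diagnosis"].to_numpy(dtype=int),
        X_test=X_test,
        y_test=test["diagnosis"].to_numpy(dtype=int),
        scaler=scaler,
    )


def fit(
    cohort: pd.DataFrame,
    split: preprocessing.SplitSpec | None = None,
    config: anfis.TrainingConfig | None = None,
    weights: features.CompositeRiskWeights = features.DEFAULT_WEIGHTS,
) -> tuple[anfis.ANFISResults, PipelineData]:
    """Train the classifier on the cohort's training partition.

    Returns the fitted results (carrying the feature scaler) and the
    prepared partitions for evaluation.
    """
    data = prepare(cohort, split, weights)
    classifier = anfis.ANFISClassifier(data.y_train, data.X_train)
    results = classifier.fit(config)
    results.scaler = data.scaler
    return results, data


def subsample_test(
    data: PipelineData, n: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Seeded stratified subsample of the test partition (features, labels).

    Mirrors evaluation protocols that score a fixed-size held-out set
    (e.g. 100 cases) drawn from a larger test split.
    """
    y = data.y_test
    if n > len(y):
        raise StratificationError(f"test partition has only {len(y)} records")
    rng = np.random.default_rng(seed)
    picks = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = int(round(n * len(members) / len(y)))
        picks.append(rng.permutation(members)[:k])
    idx = np.sort(np.concatenate(picks))
    return data.X_test.iloc[idx], y[idx]
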