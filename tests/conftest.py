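import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from anfiskit import anfis, cohort, pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The default study cohort: 4311 controls + 689 cases, seed 0."""
    return cohort.generate_cohort(cohort.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A reduced cohort (520 controls + 80 cases) for fast model tests."""
    return cohort.generate_cohort(
        cohort.CohortConfig(n_controls=520, n_cases=80, seed=7)
    )


@pytest.fixture(scope="session")
def quick_config() -> anfis.TrainingConfig:
    return anfis.TrainingConfig(max_epochs=15, early_stopping_patience=5, seed=3)


@pytest.fixture(scope="session")
def small_fit(small_cohort, quick_config):
    """A trained pipeline on the small cohort: (ANFISResults, PipelineData)."""
    return pipeline.fit(small_cohort, config=quick_config)


@pytest.fixture()
def table6_record() -> dict:
    """The worked clinical case: moderate-to-high scores, no family history."""
    return {
        "child_id": "case-1",
        "age": 4,
        "sex": "female",
        "cognitive_score": 64.45,
        "behavioral_score": 74.14,
        "motor_skills": 68.35,
        "social_interaction": 61.20,
        "family_history": 0,
        "diagnosis": 0,
    }


def tiny_model(n_features=3, n_rules=4, seed=0) -> anfis.ANFISModel:
    """A small random but valid ANFIS model for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n_mfs = 3
    centers = np.sort(rng.random((n_features, n_mfs)), axis=1)
    widths = rng.uniform(0.1, 0.4, (n_features, n_mfs))
    antecedents = rng.integers(0, n_mfs, (n_rules, n_features))
    return anfis.ANFISModel(
        centers=centers,
        widths=widths,
        antecedents=antecedents,
        coefficients=rng.normal(0, 0.5, (n_rules, n_features)),
        intercepts=rng.normal(0, 0.5, n_rules),
        feature_names=tuple(f"x{i}" for i in range(n_features)),
    )
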