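"""Seeded synthetic cohort generator for developmental-screening studies.

The screening analysis in this package assumes tabular child-assessment
records: four domain scores on a 0-100 scale (cognitive, behavioral, motor,
social interaction), integer age 1-6, sex, a binary family-history flag and
a binary diagnosis. This module generates cohorts with a prescribed
group-conditional structure — per-group truncated-normal domain scores,
per-group Bernoulli family history and sex, discrete-uniform age — so that
the whole pipeline is testable and reproducible without any external data.

The default parameters describe a cohort of 4,311 typically developing
children and 689 children with diagnosed developmental disabilities
(prevalence 13.8%), with group-conditional domain means chosen so that each
domain correlates moderately and negatively with diagnosis and family
history is the strongest single correlate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateCohortError,
    InvalidParameterError,
    SchemaError,
    UndefinedMetricError,
)

DOMAIN_COLUMNS = (
    "cognitive_score",
    "behavioral_score",
    "motor_skills",
    "social_interaction",
)

COHORT_COLUMNS = (
    "child_id",
    "age",
    "sex",
    "cognitive_score",
    "behavioral_score",
    "motor_skills",
    "social_interaction",
    "family_history",
    "diagnosis",
)


@dataclass(frozen=True)
class GroupParams:
    """Group-conditional generating parameters for one diagnostic group.

    Domain scores are truncated normals on the 0-100 scale; family history
    and female sex are Bernoulli.
    """

    mean_cognitive: float
    sd_cognitive: float
    mean_behavioral: float
    sd_behavioral: float
    mean_motor: float
    sd_motor: float
    mean_social: float
    sd_social: float
    p_family_history: float
    p_female: float

    def __post_init__(self) -> None:
        for name in ("cognitive", "behavioral", "motor", "social"):
            mean = getattr(self, f"mean_{name}")
            sd = getattr(self, f"sd_{name}")
            if not (np.isfinite(mean) and 0.0 <= mean <= 100.0):
                raise InvalidParameterError(f"mean_{name}={mean} outside [0, 100]")
            if not (np.isfinite(sd) and sd > 0.0):
                raise InvalidParameterError(f"sd_{name}={sd} must be > 0")
        for name in ("p_family_history", "p_female"):
            p = getattr(self, name)
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise InvalidParameterError(f"{name}={p} outside [0, 1]")

    def domain_mean(self, column: str) -> float:
        return getattr(self, f"mean_{_short_name(column)}")

    def domain_sd(self, column: str) -> float:
        return getattr(self, f"sd_{_short_name(column)}")


def _short_name(column: str) -> str:
    mapping = {
        "cognitive_score": "cognitive",
        "behavioral_score": "behavioral",
        "motor_skills": "motor",
        "social_interaction": "social",
    }
    try:
        return mapping[column]
    except KeyError:
        raise SchemaError(f"unknown domain column {column!r}") from None


#: Typically developing group (group 0) defaults.
TYPICAL_GROUP = GroupParams(
    mean_cognitive=60.86, sd_cognitive=14.51,
    mean_behavioral=55.82, sd_behavioral=9.38,
    mean_motor=51.08, sd_motor=7.79,
    mean_social=51.20, sd_social=11.66,
    p_family_history=0.450,
    p_female=0.517,
)

#: Developmental-disability group (group 1) defaults.
DIAGNOSED_GROUP = GroupParams(
    mean_cognitive=51.58, sd_cognitive=17.09,
    mean_behavioral=49.64, sd_behavioral=11.21,
    mean_motor=45.08, sd_motor=8.00,
    mean_social=42.13, sd_social=11.19,
    p_family_history=0.856,
    p_female=0.489,
)


@dataclass(frozen=True)
class CohortConfig:
    """Full generating configuration for one synthetic cohort.

    Group sizes may be given either explicitly (``n_controls``/``n_cases``,
    the default, which makes prevalence exact by construction) or via
    ``n_total`` and ``prevalence``, in which case the case count is the
    nearest integer to ``prevalence * n_total``.
    """

    n_controls: int = 4311
    n_cases: int = 689
    age_min: int = 1
    age_max: int = 6
    group0: GroupParams = field(default_factory=lambda: TYPICAL_GROUP)
    group1: GroupParams = field(default_factory=lambda: DIAGNOSED_GROUP)
    score_floor: float = 0.0
    score_ceiling: float = 100.0
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1:
            raise DegenerateCohortError(
                f"both groups need at least one member "
                f"(n_controls={self.n_controls}, n_cases={self.n_cases})"
            )
        if self.age_min < 1 or self.age_max < self.age_min:
            raise InvalidParameterError(
                f"need 1 <= age_min <= age_max, got [{self.age_min}, {self.age_max}]"
            )
        if not self.score_floor < self.score_ceiling:
            raise InvalidParameterError("score_floor must be below score_ceiling")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParameterError("missing_rate must be in [0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_controls + self.n_cases

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_total

    @classmethod
    def from_prevalence(cls, n_total: int, prevalence: float, **kwargs) -> "CohortConfig":
        """Build a config from a total size and a prevalence proportion.

        The diagnosed-group size is the nearest integer to
        ``prevalence * n_total`` (half rounded up), so the realised
        prevalence is deterministic, not Bernoulli.
        """
        if n_total < 2:
            raise InvalidParameterError("n_total must be at least 2")
        if not 0.0 < prevalence < 1.0:
            raise InvalidParameterError("prevalence must be in (0, 1)")
        n_cases = int(math.floor(prevalence * n_total + 0.5))
        n_controls = n_total - n_cases
        if n_cases == 0 or n_controls == 0:
            raise DegenerateCohortError(
                f"prevalence {prevalence} at n_total={n_total} rounds to an empty group"
            )
        return cls(n_controls=n_controls, n_cases=n_cases, **kwargs)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        """Build a config from a plain mapping (e.g. a parsed YAML section)."""
        raw = dict(raw)
        for key in ("group0", "group1"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = GroupParams(**raw[key])
        if "prevalence" in raw:
            n_total = raw.pop("n_total")
            prevalence = raw.pop("prevalence")
            raw.pop("n_controls", None)
            raw.pop("n_cases", None)
            return cls.from_prevalence(n_total, prevalence, **raw)
        raw.pop("n_total", None)
        return cls(**raw)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def sample_truncated_normal(
    mean: float,
    sd: float,
    low: float,
    high: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from a normal(mean, sd) conditioned on [low, high].

    Uses inverse-CDF sampling (``scipy.stats.truncnorm``), so there is no
    point mass at the bounds as clipping would produce.
    """
    for name, value in (("mean", mean), ("sd", sd), ("low", low), ("high", high)):
        if not np.isfinite(value):
            raise InvalidParameterError(f"{name}={value} is not finite")
    if sd <= 0:
        raise InvalidParameterError(f"sd={sd} must be > 0")
    if not low < high:
        raise InvalidParameterError(f"need low < high, got [{low}, {high}]")
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def truncated_normal_mean(mean: float, sd: float, low: float, high: float) -> float:
    """Analytic mean of the truncated normal (used to bound truncation bias)."""
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate one cohort as a DataFrame with the canonical column schema.

    Group membership is by fixed counts (diagnosed children first in
    generation order, then shuffled), domain scores are independent
    truncated normals within group, family history and sex are
    group-conditional Bernoulli draws, and age is discrete uniform on
    ``{age_min, ..., age_max}``. Fully reproducible from ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    frames = []
    for diagnosis, group, n in (
        (1, config.group1, config.n_cases),
        (0, config.group0, config.n_controls),
    ):
        data = {"age": rng.integers(config.age_min, config.age_max + 1, size=n)}
        data["sex"] = np.where(rng.random(n) < group.p_female, "female", "male")
        for column in DOMAIN_COLUMNS:
            data[column] = sample_truncated_normal(
                group.domain_mean(column),
                group.domain_sd(column),
                config.score_floor,
                config.score_ceiling,
                rng,
                size=n,
            )
        data["family_history"] = (rng.random(n) < group.p_family_history).astype(int)
        data["diagnosis"] = np.full(n, diagnosis, dtype=int)
        frames.append(pd.DataFrame(data))
    cohort = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cohort.insert(0, "child_id", [f"C{i:05d}" for i in range(len(cohort))])
    if config.missing_rate > 0.0:
        mask = rng.random((len(cohort), len(DOMAIN_COLUMNS))) < config.missing_rate
        for j, column in enumerate(DOMAIN_COLUMNS):
            cohort.loc[mask[:, j], column] = np.nan
    return cohort[list(COHORT_COLUMNS)]


def point_biserial(values, labels) -> float:
    """Point-biserial correlation between a numeric vector and binary labels.

    Computed as ``(M1 - M0) * sqrt(p * (1 - p)) / SD_total`` with the
    population SD; identical to the Pearson correlation of ``values`` with
    the 0/1 labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise SchemaError("values and labels must have equal length")
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("values must be finite")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise UndefinedMetricError(
            "point-biserial correlation needs both label classes present"
        )
    sd_total = values.std()  # population SD
    if sd_total == 0.0:
        raise UndefinedMetricError("values have zero variance")
    positive = labels == classes.max()
    p = positive.mean()
    m1 = values[positive].mean()
    m0 = values[~positive].mean()
    return float((m1 - m0) * math.sqrt(p * (1.0 - p)) / sd_total)


def phi_coefficient(x, y) -> float:
    """Phi association of two binary vectors (their Pearson correlation)."""
    return point_biserial(np.asarray(x, dtype=float), y)


def expected_point_biserial(
    mean0: float, sd0: float, mean1: float, sd1: float, prevalence: float
) -> float:
    """Closed-form point-biserial implied by two group normals and a mixing
    proportion (ignoring the small truncation bias)."""
    p = prevalence
    delta = mean1 - mean0
    var_total = p * sd1**2 + (1 - p) * sd0**2 + p * (1 - p) * delta**2
    return delta * math.sqrt(p * (1 - p)) / math.sqrt(var_total)


def expected_phi(p0: float, p1: float, prevalence: float) -> float:
    """Closed-form phi implied by two Bernoulli rates and a mixing proportion."""
    q = prevalence
    pbar = q * p1 + (1 - q) * p0
    return (p1 - p0) * math.sqrt(q * (1 - q)) / math.sqrt(pbar * (1 - pbar))


@dataclass
class CohortSummary:
    """Descriptive statistics of a cohort, by diagnostic group and overall."""

    n_total: int
    n_controls: int
    n_cases: int
    prevalence: float
    female_proportion: float
    domain_stats: pd.DataFrame  # index: domain; cols: mean0, sd0, mean1, sd1, mean, sd
    fh_proportion_controls: float
    fh_proportion_cases: float
    fh_proportion_overall: float
    point_biserial_with_diagnosis: dict[str, float]
    family_history_phi: float

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a one-row-per-statistic table for CSV output."""
        rows = [
            ("n_total", self.n_total),
            ("n_controls", self.n_controls),
            ("n_cases", self.n_cases),
            ("prevalence", self.prevalence),
            ("female_proportion", self.female_proportion),
            ("family_history_controls", self.fh_proportion_controls),
            ("family_history_cases", self.fh_proportion_cases),
            ("family_history_overall", self.fh_proportion_overall),
            ("family_history_phi", self.family_history_phi),
        ]
        for domain, stats_row in self.domain_stats.iterrows():
            for col, value in stats_row.items():
                rows.append((f"{domain}.{col}", value))
        for domain, r in self.point_biserial_with_diagnosis.items():
            rows.append((f"{domain}.point_biserial", r))
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Compute the descriptive summary of a cohort table.

    Requires both diagnostic classes and the canonical columns; missing
    domain cells are ignored in the moment estimates but rejected by the
    correlation computations.
    """
    missing = set(COHORT_COLUMNS) - set(records.columns) - {"child_id"}
    if missing:
        raise SchemaError(f"cohort table is missing columns: {sorted(missing)}")
    if records.empty:
        raise SchemaError("cohort table is empty")
    diagnosis = records["diagnosis"].to_numpy()
    if len(np.unique(diagnosis)) != 2:
        raise UndefinedMetricError("both diagnostic classes must be present")

    cases = records[records["diagnosis"] == 1]
    controls = records[records["diagnosis"] == 0]
    stats_rows = {}
    correlations = {}
    for column in DOMAIN_COLUMNS:
        stats_rows[column] = {
            "mean0": controls[column].mean(),
            "sd0": controls[column].std(ddof=1),
            "mean1": cases[column].mean(),
            "sd1": cases[column].std(ddof=1),
            "mean": records[column].mean(),
            "sd": records[column].std(ddof=1),
        }
        complete = records[column].notna()
        correlations[column] = point_biserial(
            records.loc[complete, column], diagnosis[complete.to_numpy()]
        )
    if records["sex"].dtype == object:
        female = (records["sex"] == "female").mean()
    else:
        female = records["sex"].mean()
    return CohortSummary(
        n_total=len(records),
        n_controls=len(controls),
        n_cases=len(cases),
        prevalence=len(cases) / len(records),
        female_proportion=float(female),
        domain_stats=pd.DataFrame.from_dict(stats_rows, orient="index"),
        fh_proportion_controls=float(controls["family_history"].mean()),
        fh_proportion_cases=float(cases["family_history"].mean()),
        fh_proportion_overall=float(records["family_history"].mean()),
        point_biserial_with_diagnosis=correlations,
        family_history_phi=phi_coefficient(
            records["family_history"].to_numpy(), diagnosis
        ),
    )
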