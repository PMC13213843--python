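"""Synthetic cohort generator: distributional fidelity and determinism."""

import io
import itertools

import numpy as np
import pytest
from scipy import stats

from anfiskit import cohort
from anfiskit.errors import (
    DegenerateCohortError,
    InvalidParameterError,
    UndefinedMetricError,
)


class TestTruncatedNormal:
    def test_vanishing_variance_collapses_to_mean(self):
        rng = np.random.default_rng(0)
        draws = cohort.sample_truncated_normal(50, 1e-9, 0, 100, rng, size=10)
        assert np.allclose(draws, 50.0, atol=1e-6)

    def test_matches_analytic_truncated_mean(self):
        rng = np.random.default_rng(1)
        draws = cohort.sample_truncated_normal(51.58, 17.09, 0, 100, rng, size=10**5)
        analytic = cohort.truncated_normal_mean(51.58, 17.09, 0, 100)
        assert abs(draws.mean() - analytic) < 0.5

    def test_respects_bounds_even_for_outside_mean(self):
        rng = np.random.default_rng(2)
        draws = cohort.sample_truncated_normal(-50, 10, 0, 100, rng, size=1000)
        assert np.all(draws >= 0) and np.all(draws <= 100)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mean": np.nan, "sd": 1, "low": 0, "high": 1},
            {"mean": 0, "sd": -1, "low": 0, "high": 1},
            {"mean": 0, "sd": 1, "low": 1, "high": 0},
            {"mean": 0, "sd": np.inf, "low": 0, "high": 1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            cohort.sample_truncated_normal(rng=np.random.default_rng(0), **kwargs)


class TestGenerateCohort:
    def test_prevalence_rounding_is_deterministic(self):
        config = cohort.CohortConfig.from_prevalence(5000, 0.138, seed=0)
        assert config.n_cases == 690
        records = cohort.generate_cohort(config)
        assert records["diagnosis"].sum() == 690

    def test_explicit_group_sizes_reproduce_study_prevalence(self, default_cohort):
        assert len(default_cohort) == 5000
        assert default_cohort["diagnosis"].sum() == 689
        assert default_cohort["diagnosis"].mean() == pytest.approx(0.1378)

    def test_type_invariants(self, default_cohort):
        for column in cohort.DOMAIN_COLUMNS:
            assert default_cohort[column].between(0, 100).all()
        assert set(default_cohort["family_history"]) <= {0, 1}
        assert set(default_cohort["diagnosis"]) == {0, 1}
        assert default_cohort["age"].between(1, 6).all()
        assert set(default_cohort["sex"]) == {"male", "female"}
        assert list(default_cohort.columns) == list(cohort.COHORT_COLUMNS)

    def test_case_group_cognitive_mean_within_three_se(self, default_cohort):
        cases = default_cohort[default_cohort["diagnosis"] == 1]
        se = 17.09 / np.sqrt(689)
        assert abs(cases["cognitive_score"].mean() - 51.58) < 3 * se

    def test_seed_determinism_byte_for_byte(self):
        config = cohort.CohortConfig(n_controls=200, n_cases=40, seed=11)
        buffers = []
        for _ in range(2):
            buffer = io.StringIO()
            cohort.generate_cohort(config).to_csv(buffer, index=False)
            buffers.append(buffer.getvalue())
        assert buffers[0] == buffers[1]

    def test_different_seeds_differ(self):
        a = cohort.generate_cohort(cohort.CohortConfig(n_controls=50, n_cases=10, seed=1))
        b = cohort.generate_cohort(cohort.CohortConfig(n_controls=50, n_cases=10, seed=2))
        assert not a.drop(columns="child_id").equals(b.drop(columns="child_id"))

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(DegenerateCohortError):
            cohort.CohortConfig(n_controls=10, n_cases=0)
        with pytest.raises(DegenerateCohortError):
            cohort.CohortConfig.from_prevalence(10, 0.01)

    def test_group_moments_recovered_within_four_se(self, default_cohort):
        groups = {0: cohort.TYPICAL_GROUP, 1: cohort.DIAGNOSED_GROUP}
        for diagnosis, params in groups.items():
            sub = default_cohort[default_cohort["diagnosis"] == diagnosis]
            for column in cohort.DOMAIN_COLUMNS:
                mu, sd = params.domain_mean(column), params.domain_sd(column)
                se = sd / np.sqrt(len(sub))
                # 0.3 covers the (bounded) truncation bias of the 0-100 clip
                assert abs(sub[column].mean() - mu) < 4 * se + 0.3

    def test_domains_independent_within_group(self, default_cohort):
        controls = default_cohort[default_cohort["diagnosis"] == 0]
        for a, b in itertools.combinations(cohort.DOMAIN_COLUMNS, 2):
            r = np.corrcoef(controls[a], controls[b])[0, 1]
            assert abs(r) < 0.05

    def test_missingness_hook_inserts_gaps(self):
        config = cohort.CohortConfig(
            n_controls=400, n_cases=100, seed=3, missing_rate=0.05
        )
        records = cohort.generate_cohort(config)
        frac = records[list(cohort.DOMAIN_COLUMNS)].isna().mean().mean()
        assert 0.02 < frac < 0.08


class TestPointBiserial:
    def test_perfect_agreement(self):
        labels = np.array([0, 1, 0, 1, 1])
        assert cohort.point_biserial(labels.astype(float), labels) == pytest.approx(1.0)

    def test_constant_values_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cohort.point_biserial([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cohort.point_biserial([1.0, 2.0, 3.0], [1, 1, 1])

    def test_matches_scipy_pearson_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        ours = cohort.point_biserial(values, labels)
        oracle = stats.pearsonr(values, labels).statistic
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_closed_form_prediction_from_group_moments(self):
        # two normal groups mixed at p should land on the closed form
        rng = np.random.default_rng(8)
        n1, n0 = 13800, 86200
        values = np.r_[rng.normal(51.58, 17.09, n1), rng.normal(60.86, 14.51, n0)]
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        expected = cohort.expected_point_biserial(60.86, 14.51, 51.58, 17.09, 0.138)
        assert expected == pytest.approx(-0.21, abs=0.005)
        assert cohort.point_biserial(values, labels) == pytest.approx(expected, abs=0.01)

    def test_phi_matches_pearson_on_binaries(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 500)
        y = (rng.random(500) < 0.3 + 0.4 * x).astype(int)
        assert cohort.phi_coefficient(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )


class TestSummarizeCohort:
    def test_hand_computed_four_record_cohort(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "child_id": ["a", "b", "c", "d"],
                "age": [1, 2, 3, 4],
                "sex": ["male", "female", "female", "male"],
                "cognitive_score": [40.0, 60.0, 50.0, 70.0],
                "behavioral_score": [45.0, 55.0, 50.0, 50.0],
                "motor_skills": [30.0, 50.0, 40.0, 60.0],
                "social_interaction": [20.0, 40.0, 60.0, 80.0],
                "family_history": [1, 0, 1, 0],
                "diagnosis": [1, 1, 0, 0],
            }
        )
        summary = cohort.summarize_cohort(records)
        assert summary.n_cases == 2 and summary.prevalence == 0.5
        assert summary.domain_stats.loc["cognitive_score", "mean1"] == 50.0
        assert summary.domain_stats.loc["cognitive_score", "mean"] == 55.0
        assert summary.fh_proportion_cases == 0.5
        assert summary.female_proportion == 0.5

    def test_weighted_group_means_compose_overall_mean(self, default_cohort):
        summary = cohort.summarize_cohort(default_cohort)
        row = summary.domain_stats.loc["motor_skills"]
        weighted = (
            row["mean0"] * summary.n_controls + row["mean1"] * summary.n_cases
        ) / summary.n_total
        assert row["mean"] == pytest.approx(weighted, abs=1e-9)

    def test_correlations_match_closed_form_predictions(self):
        # average over a few seeds so the Monte-Carlo error of each
        # correlation estimate is well inside the +/-0.03 band
        summaries = [
            cohort.summarize_cohort(
                cohort.generate_cohort(cohort.CohortConfig(seed=seed))
            )
            for seed in range(4)
        ]
        p = summaries[0].prevalence
        for column in cohort.DOMAIN_COLUMNS:
            expected = cohort.expected_point_biserial(
                cohort.TYPICAL_GROUP.domain_mean(column),
                cohort.TYPICAL_GROUP.domain_sd(column),
                cohort.DIAGNOSED_GROUP.domain_mean(column),
                cohort.DIAGNOSED_GROUP.domain_sd(column),
                p,
            )
            observed = np.mean(
                [s.point_biserial_with_diagnosis[column] for s in summaries]
            )
            assert observed == pytest.approx(expected, abs=0.03)
        mean_phi = np.mean([s.family_history_phi for s in summaries])
        assert mean_phi == pytest.approx(cohort.expected_phi(0.450, 0.856, p), abs=0.03)

    def test_single_class_rejected(self, default_cohort):
        controls = default_cohort[default_cohort["diagnosis"] == 0]
        with pytest.raises(UndefinedMetricError):
            cohort.summarize_cohort(controls)
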