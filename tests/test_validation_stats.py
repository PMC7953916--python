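"""Score-vs-outcome regression machinery: hand oracles, invariances and
parameter recovery on the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from regenscore import (
    InsufficientDataError,
    MixedScoreRegression,
    ScoreRegression,
    ValidationError,
    VariabilityTrend,
    fit_mixed_model,
    fit_score_regression,
    run_validation,
    variability_trend,
)
from regenscore.simulate import (
    OutcomeEffect,
    SimulationConfig,
    generate_outcomes,
    generate_profiles,
)


def _table(scores, values, outcome="y", **extra):
    n = len(scores)
    base = {
        "operation_id": [f"op{i}" for i in range(n)],
        "score": scores,
        "outcome_name": [outcome] * n,
        "outcome_value": values,
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestScoreRegression:
    def test_perfect_line(self):
        scores = np.arange(5)
        table = _table(scores, 2.0 * scores + 1.0)
        res = fit_score_regression(table, "y")
        assert res.score_slope == pytest.approx(2.0, rel=1e-9)
        assert res.term("intercept").estimate == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, rel=1e-9)

    def test_hand_least_squares(self):
        # (0,1),(1,3),(2,2),(3,5),(4,4): slope = Sxy/Sxx = 8/10
        table = _table([0, 1, 2, 3, 4], [1, 3, 2, 5, 4])
        res = fit_score_regression(table, "y")
        assert res.score_slope == pytest.approx(0.8, rel=1e-12)
        assert res.df_num == 1 and res.df_den == 3
        assert res.n == 5

    def test_constant_score_is_singular(self):
        table = _table([3, 3, 3, 3], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValidationError):
            fit_score_regression(table, "y")

    def test_too_few_rows(self):
        table = _table([0, 1], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_score_regression(table, "y")

    def test_row_permutation_and_centering_invariance(self):
        rng = np.random.default_rng(31)
        scores = rng.integers(0, 9, size=30)
        y = 1.5 * scores + rng.normal(0, 2, size=30)
        table = _table(scores, y)
        res = fit_score_regression(table, "y")
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = fit_score_regression(shuffled, "y")
        assert res.score_slope == pytest.approx(res2.score_slope, rel=1e-12)
        centered = _table(scores - scores.mean(), y)
        res3 = fit_score_regression(centered, "y")
        assert res3.score_slope == pytest.approx(res.score_slope, rel=1e-9)
        # closed form Sxy/Sxx
        sxx = np.sum((scores - scores.mean()) ** 2)
        sxy = np.sum((scores - scores.mean()) * (y - y.mean()))
        assert res.score_slope == pytest.approx(sxy / sxx, rel=1e-9)

    def test_clay_cofactor(self):
        rng = np.random.default_rng(37)
        scores = rng.integers(0, 9, size=40)
        clay = rng.uniform(10, 40, size=40)
        y = 2.0 * scores + 0.5 * clay + rng.normal(0, 0.1, size=40)
        table = _table(scores, y, clay_pct=clay)
        res = fit_score_regression(table, "y", include_clay=True)
        assert res.score_slope == pytest.approx(2.0, abs=0.05)
        assert res.term("clay").estimate == pytest.approx(0.5, abs=0.05)

    def test_composite_before_fit(self):
        # two replicates per operation; OLS consumes their mean
        table = pd.DataFrame(
            {
                "operation_id": ["a", "a", "b", "b", "c", "c"],
                "score": [0, 0, 1, 1, 2, 2],
                "outcome_name": ["y"] * 6,
                "outcome_value": [1.0, 3.0, 4.0, 6.0, 7.0, 9.0],
            }
        )
        res = fit_score_regression(table, "y")
        assert res.n == 3
        assert res.score_slope == pytest.approx(3.0, rel=1e-9)

    def test_estimator_predict(self):
        est = ScoreRegression().fit(np.arange(5.0)[:, None],
                                    2 * np.arange(5.0) + 1)
        assert est.predict([[10.0]])[0] == pytest.approx(21.0, rel=1e-9)

    def test_score_varying_within_operation_rejected(self):
        table = pd.DataFrame(
            {
                "operation_id": ["a", "a", "b"],
                "score": [0, 1, 2],
                "outcome_name": ["y"] * 3,
                "outcome_value": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValidationError):
            fit_score_regression(table, "y")


class TestMixedModel:
    def _nested_table(self, farm_sd, n_farms=30, n_fields=3, slope=1.5,
                      seed=0):
        config = SimulationConfig(
            n_operations=n_farms,
            effects={
                "y": OutcomeEffect(
                    intercept=10.0, slope_per_score_unit=slope,
                    farm_sd=farm_sd, residual_sd=1.0,
                )
            },
            n_fields_per_operation=n_fields,
            seed=seed,
        )
        profiles = generate_profiles(config)
        return generate_outcomes(profiles, config)

    def test_boundary_variance_estimate_collapses_to_ols(self):
        """When REML estimates the farm variance at the zero boundary
        the fit falls back to OLS, whose fixed effect it then matches
        exactly.  (With a true zero variance the REML estimate lands on
        the boundary in roughly half of realizations; this dataset is
        one of them.)"""
        table = self._nested_table(farm_sd=0.0, seed=2)
        lmm = fit_mixed_model(table, "y")
        ols = fit_score_regression(table, "y", composite=False)
        assert lmm.score_slope == pytest.approx(ols.score_slope, abs=1e-6)
        assert lmm.model_kind == "ols"
        assert lmm.note != ""

    def test_recovers_generating_slope(self):
        table = self._nested_table(farm_sd=2.0, n_farms=40, n_fields=4,
                                   slope=1.5, seed=11)
        res = fit_mixed_model(table, "y")
        se = res.term("score").std_error
        assert abs(res.score_slope - 1.5) < 2 * se
        assert res.model_kind == "lmm"

    def test_missing_grouping_column_rejected(self):
        table = _table([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0]).drop(
            columns=[]
        )
        with pytest.raises(ValidationError):
            fit_mixed_model(table.drop(columns=["operation_id"]), "y")

    def test_single_observation_per_farm_falls_back(self):
        table = self._nested_table(farm_sd=1.0, n_farms=30, n_fields=1,
                                   seed=5)
        with pytest.warns(UserWarning, match="single observation"):
            res = fit_mixed_model(table, "y")
        assert res.model_kind == "ols"

    def test_month_fixed_factor(self):
        config = SimulationConfig(
            n_operations=24,
            effects={
                "y": OutcomeEffect(intercept=5.0, slope_per_score_unit=1.0,
                                   farm_sd=1.0, residual_sd=0.5)
            },
            months=["jun", "jul", "aug"],
            month_effects={"jul": 2.0, "aug": 4.0},
            seed=9,
        )
        profiles = generate_profiles(config)
        table = generate_outcomes(profiles, config)
        res = fit_mixed_model(table, "y", include_month=True)
        assert abs(res.score_slope - 1.0) < 3 * res.term("score").std_error
        month_terms = [t for t in res.terms if "month" in t.name.lower()]
        assert len(month_terms) == 2


class TestVariabilityTrend:
    def test_flat_cv(self):
        # three levels, constant CV 0.2 by construction
        rows = []
        for level, mean in [(0, 10.0), (1, 20.0), (2, 30.0)]:
            sd = 0.2 * mean
            # two operations symmetric about the mean: SD/mean exact
            for j, v in enumerate(
                [mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)]
            ):
                rows.append((f"op{level}{j}", level, v))
        table = _table(
            [r[1] for r in rows], [r[2] for r in rows],
        )
        table["operation_id"] = [r[0] for r in rows]
        res = variability_trend(table, "y")
        assert res.score_slope == pytest.approx(0.0, abs=1e-9)

    def test_collinear_cv_levels(self):
        rows = []
        for level, cv in [(0, 0.1), (1, 0.2), (2, 0.3)]:
            mean = 10.0
            sd = cv * mean
            for j, v in enumerate(
                [mean - sd / np.sqrt(2), mean + sd / np.sqrt(2)]
            ):
                rows.append((f"op{level}{j}", level, v))
        table = _table([r[1] for r in rows], [r[2] for r in rows])
        table["operation_id"] = [r[0] for r in rows]
        res = variability_trend(table, "y")
        assert res.score_slope == pytest.approx(0.1, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.df_num == 1 and res.df_den == 1

    def test_too_few_levels(self):
        table = _table([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
        table["operation_id"] = ["a", "b", "c", "d"]
        with pytest.raises(InsufficientDataError):
            variability_trend(table, "y")

    def test_zero_mean_level_undefined(self):
        table = _table(
            [0, 0, 1, 1, 2, 2], [-1.0, 1.0, 3.0, 4.0, 5.0, 6.0]
        )
        table["operation_id"] = list("abcdef")
        with pytest.raises(ValidationError):
            variability_trend(table, "y")

    def test_estimator_direct(self):
        est = VariabilityTrend().fit(
            [0, 0, 1, 1, 2, 2], [10.0, 12.0, 10.0, 14.0, 10.0, 18.0]
        )
        assert est.result_.score_slope > 0


class TestRunValidation:
    def test_empty_spec(self):
        table = _table([0, 1, 2], [1.0, 2.0, 3.0])
        out = run_validation(table, [])
        assert len(out) == 0
        assert out.attrs["n_models_fitted"] == 0

    def test_perfect_line_positive(self):
        scores = np.arange(6)
        table = _table(scores, 3.0 * scores + 2.0)
        out = run_validation(table, [{"outcome_name": "y", "model_kind": "ols"}])
        assert out.loc[0, "sign"] == "positive"
        assert out.loc[0, "slope_p"] < 1e-6

    def test_failures_captured_not_raised(self):
        table = _table([0, 1, 2], [1.0, 2.0, 3.0])
        out = run_validation(
            table,
            [
                {"outcome_name": "y", "model_kind": "ols"},
                {"outcome_name": "missing", "model_kind": "ols"},
            ],
        )
        assert out.loc[0, "error"] == ""
        assert "InsufficientDataError" in out.loc[1, "error"]
        assert out.attrs["n_models_fitted"] == 1

    def test_scores_merged_from_records(self):
        outcomes = pd.DataFrame(
            {
                "operation_id": ["a", "b", "c", "d"],
                "outcome_name": ["y"] * 4,
                "outcome_value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        scores = pd.DataFrame(
            {"operation_id": list("abcd"), "composite_score": [0, 1, 2, 3]}
        )
        out = run_validation(
            outcomes, [{"outcome_name": "y"}], scores=scores
        )
        assert out.loc[0, "slope"] == pytest.approx(1.0, rel=1e-9)
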