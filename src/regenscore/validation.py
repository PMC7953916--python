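"""Score-versus-outcome validation statistics.

The scoring rubric is validated by regressing each response variable on
the composite regenerative score: ordinary least squares on one
composited value per operation (with soil clay % as a co-factor where it
matters), linear mixed models with farm/field random intercepts (and a
month fixed factor) where an operation was resampled, and a
coefficient-of-variation trend that asks whether outcome variability
grows with the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError, ValidationError

ALPHA = 0.05

OUTCOME_COLUMNS = (
    "operation_id",
    "score",
    "outcome_name",
    "outcome_value",
)


@dataclass
class Term:
    name: str
    estimate: float
    std_error: float
    t: float
    p: float


@dataclass
class RegressionResult:
    """Fitted-model summary: per-term estimates and the overall test."""

    outcome_name: str
    terms: List[Term]
    f_stat: float
    df_num: int
    df_den: float
    model_p: float
    r_squared: float
    n: int
    model_kind: str
    note: str = ""

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def score_slope(self) -> float:
        return self.term("score").estimate

    @property
    def score_p(self) -> float:
        return self.term("score").p

    def sign_at_alpha(self, alpha: float = ALPHA) -> str:
        """'positive', 'negative' or 'ns' for the score term."""
        t = self.term("score")
        if t.p >= alpha:
            return "ns"
        return "positive" if t.estimate > 0 else "negative"

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "model_kind": self.model_kind,
            "n": self.n,
            "f_stat": self.f_stat,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "model_p": self.model_p,
            "r_squared": self.r_squared,
            "terms": [vars(t) for t in self.terms],
            "note": self.note,
        }


def _check_outcome_table(table: pd.DataFrame) -> None:
    missing = [c for c in OUTCOME_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"outcome table missing columns: {missing}")
    if table["outcome_value"].isna().any():
        raise ValidationError("outcome table contains missing outcome values")
    spread = table.groupby("operation_id")["score"].nunique()
    if (spread > 1).any():
        bad = spread[spread > 1].index.tolist()
        raise ValidationError(
            f"score varies within operation(s): {bad}; scores are an "
            "operation-level attribute"
        )


class ScoreRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares of an outcome on the composite score.

    ``fit(X, y)`` takes ``X`` of shape (n, 1) — the score — or (n, 2)
    with clay % in the second column when ``include_clay=True``.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients
    result_ : RegressionResult
    """

    def __init__(self, include_clay: bool = False, outcome_name: str = "y"):
        self.include_clay = include_clay
        self.outcome_name = outcome_name

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        want = 2 if self.include_clay else 1
        if X.shape[1] != want:
            raise ValidationError(
                f"expected {want} design column(s), got {X.shape[1]}"
            )
        n = X.shape[0]
        if n < 3:
            raise InsufficientDataError(
                f"need at least 3 observations, got {n}"
            )
        if np.ptp(X[:, 0]) == 0:
            raise ValidationError(
                "singular design: the score is constant across operations"
            )
        design = sm.add_constant(X, has_constant="add")
        fit = sm.OLS(y, design).fit()
        names = ["intercept", "score"] + (
            ["clay"] if self.include_clay else []
        )
        terms = [
            Term(
                name=names[i],
                estimate=float(fit.params[i]),
                std_error=float(fit.bse[i]),
                t=float(fit.tvalues[i]),
                p=float(fit.pvalues[i]),
            )
            for i in range(len(names))
        ]
        self.coef_ = fit.params[1:]
        self.intercept_ = float(fit.params[0])
        self.n_features_in_ = X.shape[1]
        self.result_ = RegressionResult(
            outcome_name=self.outcome_name,
            terms=terms,
            f_stat=float(fit.fvalue),
            df_num=int(fit.df_model),
            df_den=float(fit.df_resid),
            model_p=float(fit.f_pvalue),
            r_squared=float(fit.rsquared),
            n=n,
            model_kind="ols",
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


class MixedScoreRegression(BaseEstimator):
    """Linear mixed model of an outcome on the score with random
    intercepts for farm (and optionally field within farm) and an
    optional month fixed factor.  Restricted maximum likelihood.

    When the random variance estimates to zero — detected by a
    restricted-likelihood-ratio comparison against the zero-variance
    model, which is robust to the optimizer stopping just short of the
    boundary — or when every group holds a single observation, making
    the variance inestimable, the fit falls back to ordinary least
    squares on the same rows and says so in ``result_.note``.
    """

    #: REML log-likelihood-ratio statistic below which the fitted random
    #: variance is a boundary (zero) estimate, triggering the OLS fallback
    collapse_lrt_tol = 1e-3

    def __init__(
        self,
        include_month: bool = False,
        nested_field: bool = False,
        outcome_name: str = "y",
    ):
        self.include_month = include_month
        self.nested_field = nested_field
        self.outcome_name = outcome_name

    def fit(self, X, y, groups, fields=None, months=None):
        score = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        n = len(y)
        if len(np.unique(groups)) < 2:
            raise ValidationError("need at least 2 farms for a mixed model")
        if np.ptp(score) == 0:
            raise ValidationError("singular design: constant score")
        df = pd.DataFrame({"y": y, "score": score, "farm": groups})
        formula = "y ~ score"
        if self.include_month:
            if months is None:
                raise ValidationError("include_month=True requires months")
            df["month"] = np.asarray(months)
            formula += " + C(month)"
        vc = None
        if self.nested_field:
            if fields is None:
                raise ValidationError("nested_field=True requires fields")
            df["field"] = np.asarray(fields)
            vc = {"field": "0 + C(field)"}

        sizes = df.groupby("farm").size()
        if (sizes == 1).all():
            warnings.warn(
                "every farm has a single observation; farm variance is "
                "inestimable, falling back to ordinary least squares",
                stacklevel=2,
            )
            return self._ols_fallback(df, "one observation per farm")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(
                    formula, data=df, groups=df["farm"], vc_formula=vc
                )
                fit = model.fit(reml=True)
            except Exception:
                return self._ols_fallback(df, "mixed-model fit failed")

        re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
        vc_var = float(np.sum(fit.vcomp)) if fit.vcomp.size else 0.0
        if self._boundary_lrt(model, fit) < self.collapse_lrt_tol:
            return self._ols_fallback(
                df, "random variance estimated at zero; collapsed to ols"
            )

        terms = []
        for name in fit.fe_params.index:
            pretty = "intercept" if name == "Intercept" else name
            terms.append(
                Term(
                    name=pretty,
                    estimate=float(fit.fe_params[name]),
                    std_error=float(fit.bse_fe[name]),
                    t=float(fit.tvalues[name]),
                    p=float(fit.pvalues[name]),
                )
            )
        score_t = next(t for t in terms if t.name == "score")
        fitted = np.asarray(fit.fittedvalues, dtype=float)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        k = len(fit.fe_params)
        self.random_variance_ = re_var
        self.vc_variance_ = vc_var
        self.coef_ = np.array([score_t.estimate])
        self.result_ = RegressionResult(
            outcome_name=self.outcome_name,
            terms=terms,
            f_stat=float(score_t.t**2),
            df_num=1,
            df_den=float(n - k),
            model_p=float(score_t.p),
            r_squared=max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0,
            n=n,
            model_kind="lmm",
        )
        return self

    @staticmethod
    def _boundary_lrt(model, fit) -> float:
        """REML likelihood-ratio statistic of the fitted random variance
        against (numerically) zero variance; ~0 means the estimate sits
        on the zero boundary."""
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        k_vc = len(fit.vcomp) if fit.vcomp is not None else 0
        p0 = MixedLMParams.from_components(
            fe_params=np.asarray(fit.fe_params, dtype=float),
            cov_re=np.full((1, 1), 1e-10),
            vcomp=np.full(k_vc, 1e-10) if k_vc else None,
        )
        try:
            ll0 = model.loglike(p0, profile_fe=True)
        except Exception:
            return np.inf
        return 2.0 * (fit.llf - ll0)

    def _ols_fallback(self, df: pd.DataFrame, note: str):
        cols = ["score"]
        design = df[cols].to_numpy(dtype=float)
        if self.include_month:
            dummies = pd.get_dummies(df["month"], prefix="month", drop_first=True)
            design = np.column_stack([design, dummies.to_numpy(dtype=float)])
            cols = cols + list(dummies.columns)
        y = df["y"].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(design, has_constant="add")).fit()
        names = ["intercept"] + cols
        terms = [
            Term(
                name=names[i],
                estimate=float(fit.params[i]),
                std_error=float(fit.bse[i]),
                t=float(fit.tvalues[i]),
                p=float(fit.pvalues[i]),
            )
            for i in range(len(names))
        ]
        self.random_variance_ = 0.0
        self.vc_variance_ = 0.0
        self.coef_ = np.array([terms[1].estimate])
        self.result_ = RegressionResult(
            outcome_name=self.outcome_name,
            terms=terms,
            f_stat=float(fit.fvalue),
            df_num=int(fit.df_model),
            df_den=float(fit.df_resid),
            model_p=float(fit.f_pvalue),
            r_squared=float(fit.rsquared),
            n=len(y),
            model_kind="ols",
            note=note,
        )
        return self


class VariabilityTrend(BaseEstimator):
    """Regression of the coefficient of variation (SD/mean of the outcome
    per integer score level) on the score: does performance become more
    variable as operations grow more regenerative?

    Requires >= 3 score levels with >= 2 operations each; levels with a
    zero mean have an undefined CV and raise.
    """

    min_levels = 3
    min_per_level = 2

    def __init__(self, outcome_name: str = "y"):
        self.outcome_name = outcome_name

    def fit(self, scores, values):
        scores = np.asarray(scores)
        values = np.asarray(values, dtype=float)
        levels, cvs = [], []
        for level in np.unique(scores):
            v = values[scores == level]
            if len(v) < self.min_per_level:
                continue
            mean = v.mean()
            if mean == 0:
                raise ValidationError(
                    f"score level {level}: zero mean, CV undefined"
                )
            levels.append(float(level))
            cvs.append(float(v.std(ddof=1) / mean))
        if len(levels) < self.min_levels:
            raise InsufficientDataError(
                f"need >= {self.min_levels} score levels with >= "
                f"{self.min_per_level} operations each, got {len(levels)}"
            )
        self.levels_ = np.array(levels)
        self.cv_ = np.array(cvs)
        design = sm.add_constant(self.levels_)
        fit = sm.OLS(self.cv_, design).fit()
        terms = [
            Term("intercept", float(fit.params[0]), float(fit.bse[0]),
                 float(fit.tvalues[0]), float(fit.pvalues[0])),
            Term("score", float(fit.params[1]), float(fit.bse[1]),
                 float(fit.tvalues[1]), float(fit.pvalues[1])),
        ]
        self.coef_ = np.array([terms[1].estimate])
        self.result_ = RegressionResult(
            outcome_name=self.outcome_name,
            terms=terms,
            f_stat=float(fit.fvalue),
            df_num=1,
            df_den=float(len(levels) - 2),
            model_p=float(fit.f_pvalue),
            r_squared=float(fit.rsquared),
            n=len(levels),
            model_kind="cv_trend",
        )
        return self


# ---------------------------------------------------------------------------
# OutcomeTable-level wrappers


def _composite_per_operation(
    sub: pd.DataFrame, include_clay: bool
) -> pd.DataFrame:
    agg = {"outcome_value": "mean", "score": "first"}
    if include_clay:
        agg["clay_pct"] = "mean"
    return sub.groupby("operation_id", sort=True).agg(agg).reset_index()


def fit_score_regression(
    table: pd.DataFrame,
    outcome_name: str,
    include_clay: bool = False,
    composite: bool = True,
) -> RegressionResult:
    """OLS of one outcome on intercept + score (+ clay).

    Replicate rows are composited (averaged) to one value per operation
    by default, matching how plot values enter the regressions; pass
    ``composite=False`` to fit on raw replicate rows.
    """
    _check_outcome_table(table)
    sub = table[table["outcome_name"] == outcome_name]
    if len(sub) == 0:
        raise InsufficientDataError(f"no rows for outcome {outcome_name!r}")
    if include_clay:
        if "clay_pct" not in sub.columns or sub["clay_pct"].isna().any():
            raise ValidationError(
                f"include_clay=True but clay_pct missing for {outcome_name!r}"
            )
    data = _composite_per_operation(sub, include_clay) if composite else sub
    cols = ["score"] + (["clay_pct"] if include_clay else [])
    X = data[cols].to_numpy(dtype=float)
    y = data["outcome_value"].to_numpy(dtype=float)
    est = ScoreRegression(include_clay=include_clay, outcome_name=outcome_name)
    est.fit(X, y)
    return est.result_


def fit_mixed_model(
    table: pd.DataFrame,
    outcome_name: str,
    include_month: bool = False,
    nested_field: bool = False,
) -> RegressionResult:
    """Linear mixed model of one outcome on the score with a random farm
    intercept (optionally field within farm) and an optional month fixed
    factor; raw replicate rows, REML estimation."""
    _check_outcome_table(table)
    sub = table[table["outcome_name"] == outcome_name]
    if len(sub) == 0:
        raise InsufficientDataError(f"no rows for outcome {outcome_name!r}")
    if nested_field and "field_or_plot_id" not in sub.columns:
        raise ValidationError("nested_field=True requires field_or_plot_id")
    if include_month and (
        "month" not in sub.columns or sub["month"].isna().any()
    ):
        raise ValidationError("include_month=True requires a month column")
    est = MixedScoreRegression(
        include_month=include_month,
        nested_field=nested_field,
        outcome_name=outcome_name,
    )
    est.fit(
        sub["score"].to_numpy(),
        sub["outcome_value"].to_numpy(dtype=float),
        groups=sub["operation_id"].to_numpy(),
        fields=sub["field_or_plot_id"].to_numpy() if nested_field else None,
        months=sub["month"].to_numpy() if include_month else None,
    )
    return est.result_


def variability_trend(table: pd.DataFrame, outcome_name: str) -> RegressionResult:
    """CV-versus-score trend for one outcome (operations composited
    first, then SD/mean per integer score level)."""
    _check_outcome_table(table)
    sub = table[table["outcome_name"] == outcome_name]
    if len(sub) == 0:
        raise InsufficientDataError(f"no rows for outcome {outcome_name!r}")
    data = _composite_per_operation(sub, include_clay=False)
    est = VariabilityTrend(outcome_name=outcome_name)
    est.fit(data["score"].to_numpy(), data["outcome_value"].to_numpy(dtype=float))
    return est.result_


def run_validation(
    outcomes: pd.DataFrame,
    model_specs: Sequence[dict],
    scores: Optional[pd.DataFrame] = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Batch driver: one fitted model per spec entry.

    Each entry: ``{"outcome_name": str, "model_kind": "ols"|"lmm"|
    "cv_trend", "include_clay": bool, "include_month": bool,
    "nested_field": bool}``.  If *scores* is given (operation_id,
    composite_score), it is merged onto the outcome table first.
    Per-entry failures are captured in the ``error`` column; the batch
    never aborts.  The summary reports the number of models fitted; no
    multiple-testing correction is applied.
    """
    table = outcomes.copy()
    if scores is not None:
        table = table.drop(columns=["score"], errors="ignore").merge(
            scores[["operation_id", "composite_score"]].rename(
                columns={"composite_score": "score"}
            ),
            on="operation_id",
            how="left",
        )
        if table["score"].isna().any():
            missing = table.loc[
                table["score"].isna(), "operation_id"
            ].unique().tolist()
            raise ValidationError(f"no score for operation(s): {missing}")
    rows = []
    for entry in model_specs:
        name = entry["outcome_name"]
        kind = entry.get("model_kind", "ols")
        row = {"outcome_name": name, "model_kind": kind}
        try:
            if kind == "ols":
                res = fit_score_regression(
                    table, name, include_clay=entry.get("include_clay", False)
                )
            elif kind == "lmm":
                res = fit_mixed_model(
                    table,
                    name,
                    include_month=entry.get("include_month", False),
                    nested_field=entry.get("nested_field", False),
                )
            elif kind == "cv_trend":
                res = variability_trend(table, name)
            else:
                raise ValidationError(f"unknown model kind {kind!r}")
        except Exception as exc:  # captured per row, batch continues
            row.update({"error": f"{type(exc).__name__}: {exc}"})
            rows.append(row)
            continue
        row.update(
            {
                "slope": res.score_slope,
                "slope_p": res.score_p,
                "sign": res.sign_at_alpha(alpha),
                "marginal": bool(alpha < res.score_p <= 0.10),
                "f_stat": res.f_stat,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "model_p": res.model_p,
                "r_squared": res.r_squared,
                "n": res.n,
                "fitted_kind": res.model_kind,
                "note": res.note,
                "error": "",
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out) and "error" in out.columns:
        out.attrs["n_models_fitted"] = int((out["error"] == "").sum())
    else:
        out.attrs["n_models_fitted"] = 0
    out.attrs["alpha"] = alpha
    return out
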