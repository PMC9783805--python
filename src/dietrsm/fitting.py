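"""Least-squares fitting of second-order models with regression diagnostics.

The datapoint for fitting is the per-run mean of replicate measurements.
Fitting itself is ordinary least squares on the full second-order basis
(delegated to statsmodels); on top of the fit this module computes the
diagnostics used to judge and clean response-surface fits:

* leverage (hat-matrix diagonal),
* externally studentized residuals (ESR) — each residual scaled by an
  error-variance estimate that excludes the point itself, so a single
  aberrant run cannot mask its own discrepancy,
* PRESS and predicted R² via the leave-one-out identity e_i / (1 - h_ii),
* adequate precision, the signal-to-noise ratio of the predicted range,
  (max yhat - min yhat) / sqrt(p * MSE / n), with > 4 the conventional
  bar for a model usable for navigation of the design space.

Outlying runs are flagged when |ESR| exceeds a threshold (default 3) and
can be excluded and the model refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Factor
from .errors import (
    DimensionError,
    InsufficientDataError,
    SingularDesignError,
)
from .models import ACTUAL, CODED, QuadraticModel, basis_matrix, term_names

__all__ = [
    "MeasurementTable",
    "FitResult",
    "AnovaReport",
    "run_means",
    "fit_quadratic",
    "fit_response",
    "anova",
    "flag_outliers",
    "refit_excluding",
]

#: canonical long-format measurement columns (factor columns in between)
MEASUREMENT_COLUMNS = ("run_id", "replicate_id", "response", "value")


class MeasurementTable:
    """Thin wrapper over a long-format replicate table.

    Columns: ``run_id``, one column per factor (actual units),
    ``replicate_id``, ``response``, ``value``.  Each run_id must map to a
    single factor-level combination.
    """

    def __init__(self, data: pd.DataFrame, factors: list[Factor]):
        required = set(MEASUREMENT_COLUMNS) | {f.name for f in factors}
        missing = required - set(data.columns)
        if missing:
            raise DimensionError(f"measurement table lacks columns {sorted(missing)}")
        levels = data.groupby("run_id")[[f.name for f in factors]].nunique()
        if (levels > 1).any().any():
            raise DimensionError("a run_id maps to more than one factor-level combination")
        self.data = data.reset_index(drop=True)
        self.factors = list(factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def responses(self) -> list[str]:
        return sorted(self.data["response"].unique())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: list[Factor]) -> "MeasurementTable":
        return cls(pd.read_csv(path), factors)


def run_means(table: MeasurementTable, response: str) -> pd.DataFrame:
    """Collapse replicates to one datapoint per run: the replicate mean.

    Returns a frame with run_id, the factor columns, ``n_replicates`` and
    the mean ``value``, sorted by run_id.
    """
    sub = table.data[table.data["response"] == response]
    if sub.empty:
        raise InsufficientDataError(f"no measurements for response {response!r}")
    grouped = (
        sub.groupby("run_id")
        .agg(**{n: (n, "first") for n in table.factor_names},
             n_replicates=("value", "size"), value=("value", "mean"))
        .reset_index()
        .sort_values("run_id", ignore_index=True)
    )
    return grouped


@dataclass
class FitResult:
    """A fitted quadratic model plus its residual diagnostics."""

    model: QuadraticModel
    run_ids: np.ndarray
    levels: np.ndarray  # (n, k) in the model's representation
    response: np.ndarray  # per-run mean datapoints
    fitted: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    esr: np.ndarray
    mse: float
    df_residual: int
    coefficient_covariance: np.ndarray
    excluded_run_ids: list = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.response)

    def predict(self, levels, with_se: bool = False):
        """Predict the mean response; with_se adds the mean-prediction SE."""
        if with_se:
            return self.model.predict(levels, covariance=self.coefficient_covariance)
        return self.model.predict(levels)

    def confidence_band(self, levels, level: float = 0.95):
        """(yhat, lower, upper) t-based confidence band for the mean prediction."""
        yhat, se = self.model.predict(levels, covariance=self.coefficient_covariance)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df_residual)
        return yhat, yhat - tcrit * se, yhat + tcrit * se


def _near_perfect(sse: float, y: np.ndarray) -> bool:
    """Residual sum of squares at machine-noise level relative to y."""
    scale = float(np.mean(y**2)) + np.finfo(float).tiny
    return sse <= 1e-18 * scale * len(y)


def _external_studentized(residuals, leverage, mse, n, p):
    """Closed-form leave-one-out studentized residuals.

    MSE_(i) = ((n-p)*MSE - e_i^2/(1-h_i)) / (n-p-1); t_i = e_i /
    sqrt(MSE_(i)*(1-h_i)).  Algebraically identical to refitting without
    point i.
    """
    one_minus_h = 1.0 - leverage
    df = n - p
    if df <= 1:
        return np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse_i = (df * mse - residuals**2 / one_minus_h) / (df - 1)
        mse_i = np.clip(mse_i, 0.0, None)
        t = residuals / np.sqrt(mse_i * one_minus_h)
    t[~np.isfinite(t)] = 0.0 if mse == 0 else t[~np.isfinite(t)]
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def fit_quadratic(
    design_levels,
    responses,
    representation: str = ACTUAL,
    factors: list[Factor] | None = None,
    run_ids=None,
    response_name: str = "",
    excluded_run_ids: list | None = None,
) -> FitResult:
    """OLS fit of the full second-order polynomial to per-run datapoints.

    Parameters
    ----------
    design_levels
        (n, k) factor levels in ``representation`` units.
    responses
        n per-run mean response values.
    factors
        Factor metadata; required for later representation conversion.
    """
    x = np.atleast_2d(np.asarray(design_levels, float))
    y = np.asarray(responses, float)
    n, k = x.shape
    if factors is None:
        factors = [Factor(f"x{i+1}", 0.0, 1.0) for i in range(k)]
    if len(factors) != k:
        raise DimensionError(f"{k} level columns but {len(factors)} factors")
    if run_ids is None:
        run_ids = np.arange(1, n + 1)
    run_ids = np.asarray(run_ids)
    if len(y) != n:
        raise DimensionError("responses and design_levels disagree on n")

    p = 1 + 2 * k + k * (k - 1) // 2
    if n <= p:
        raise InsufficientDataError(
            f"need more than p={p} datapoints for the second-order model, got {n}"
        )
    X = basis_matrix(x)
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            "design points do not support the full second-order basis"
        )

    ols = sm.OLS(y, X).fit()
    fitted = np.asarray(ols.fittedvalues)
    resid = y - fitted
    hat = np.asarray(ols.get_influence().hat_matrix_diag)
    df_resid = int(ols.df_resid)
    mse = float(ols.ssr / df_resid)
    if _near_perfect(float(ols.ssr), y):
        esr = np.zeros(n)  # residuals are numerical noise, not discrepancies
    else:
        esr = _external_studentized(resid, hat, mse, n, p)
    # scale-free covariance * MSE = coefficient covariance
    cov = np.asarray(ols.normalized_cov_params) * mse

    model = QuadraticModel.from_coefficients(
        np.asarray(ols.params), factors, representation, response_name
    )
    return FitResult(
        model=model,
        run_ids=run_ids,
        levels=x,
        response=y,
        fitted=fitted,
        residuals=resid,
        leverage=hat,
        esr=esr,
        mse=mse,
        df_residual=df_resid,
        coefficient_covariance=cov,
        excluded_run_ids=list(excluded_run_ids or []),
    )


def fit_response(
    table: MeasurementTable,
    response: str,
    representation: str = ACTUAL,
    exclude_run_ids: list | None = None,
) -> FitResult:
    """Fit one response from a replicate table (datapoint = run mean)."""
    means = run_means(table, response)
    if exclude_run_ids:
        means = means[~means["run_id"].isin(exclude_run_ids)].reset_index(drop=True)
    levels = means[table.factor_names].to_numpy(float)
    if representation == CODED:
        from .design import to_coded

        levels = to_coded(table.factors, levels)
    return fit_quadratic(
        levels,
        means["value"].to_numpy(float),
        representation=representation,
        factors=table.factors,
        run_ids=means["run_id"].to_numpy(),
        response_name=response,
        excluded_run_ids=exclude_run_ids,
    )


@dataclass
class AnovaReport:
    """Whole-model and per-term F tests plus fit-quality statistics."""

    overall_f: float
    overall_p: float
    per_term: pd.DataFrame  # index term, columns F, p
    r2: float
    r2_adjusted: float
    r2_predicted: float
    press: float
    adequate_precision: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": "model", "F": self.overall_f, "p": self.overall_p}]
        for term, row in self.per_term.iterrows():
            rows.append({"term": term, "F": row["F"], "p": row["p"]})
        out = pd.DataFrame(rows)
        for name in ("r2", "r2_adjusted", "r2_predicted", "press", "adequate_precision"):
            out[name] = getattr(self, name)
        return out


def anova(fit: FitResult) -> AnovaReport:
    """ANOVA and fit-quality diagnostics for a quadratic fit.

    Per-term tests are partial (type-III) single-df F tests: the squared
    t statistic of each coefficient, equivalent to dropping that one
    column from the full basis.  Predicted R² is 1 - PRESS/SStot with
    PRESS from the leave-one-out identity; adequate precision is the
    predicted-range signal-to-noise ratio.
    """
    y = fit.response
    n = fit.n_points
    p = fit.model.p
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float((fit.residuals**2).sum())
    ssr = sst - sse
    df_model = p - 1
    df_resid = fit.df_residual

    if _near_perfect(sse, y):
        # zero residual variance: report R²=1, zero p-values; adequate
        # precision is infinite unless the predictions are themselves flat
        terms = term_names(fit.model.factor_names)
        per_term = pd.DataFrame(
            {"F": np.inf, "p": 0.0}, index=pd.Index(terms, name="term")
        )
        signal = np.ptp(fit.fitted) > 1e-8 * np.sqrt(np.mean(y**2) + 1e-300)
        return AnovaReport(
            overall_f=np.inf,
            overall_p=0.0,
            per_term=per_term,
            r2=1.0,
            r2_adjusted=1.0,
            r2_predicted=1.0,
            press=0.0,
            adequate_precision=np.inf if signal else 0.0,
        )

    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    overall_f = (ssr / df_model) / fit.mse
    overall_p = float(stats.f.sf(overall_f, df_model, df_resid))

    se_coef = np.sqrt(np.diag(fit.coefficient_covariance))
    with np.errstate(divide="ignore"):
        t = fit.model.coefficients() / se_coef
    f_term = t**2
    p_term = stats.f.sf(f_term, 1, df_resid)
    per_term = pd.DataFrame(
        {"F": f_term, "p": p_term},
        index=pd.Index(term_names(fit.model.factor_names), name="term"),
    )

    loo = fit.residuals / (1.0 - fit.leverage)
    press = float((loo**2).sum())
    r2_pred = 1.0 - press / sst if sst > 0 else 1.0

    adequate = float(
        (fit.fitted.max() - fit.fitted.min()) / np.sqrt(p * fit.mse / n)
    )
    return AnovaReport(
        overall_f=float(overall_f),
        overall_p=overall_p,
        per_term=per_term,
        r2=float(r2),
        r2_adjusted=float(r2_adj),
        r2_predicted=float(r2_pred),
        press=press,
        adequate_precision=adequate,
    )


def flag_outliers(fit: FitResult, threshold: float = 3.0) -> list:
    """run_ids whose externally studentized residual exceeds ``threshold``."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    mask = np.abs(fit.esr) > threshold
    return [rid for rid, m in zip(fit.run_ids, mask) if m]


def refit_excluding(
    table: MeasurementTable,
    response: str,
    run_ids: list,
    representation: str = ACTUAL,
) -> FitResult:
    """Refit a response with the given runs excluded (recorded on the result)."""
    return fit_response(
        table, response, representation=representation, exclude_run_ids=list(run_ids)
    )
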