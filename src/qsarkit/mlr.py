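"""Ordinary least-squares multilinear regression with ANOVA and diagnostics.

The regression always includes an intercept (the modelled equations do).
Rank deficiency is detected through the condition number of the
column-scaled design matrix and reported loudly, naming the dependent
columns, rather than silently pseudo-inverted.

Conventions: the ANOVA decomposition is about the mean
(SS_total = SS_regression + SS_residual); the F test is upper-tail;
coefficient t-tests are two-sided.  Standardized residuals divide raw
residuals by s = sqrt(SS_res / df_residual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ActivitySeries,
    DescriptorTable,
    DomainError,
    LinearModel,
    SingularityError,
)

__all__ = [
    "AnovaTable",
    "FitSummary",
    "fit_ols",
    "anova",
    "anova_from_sums",
    "r2_adjusted",
    "standardized_residuals",
    "fit_summary",
    "coefficient_table",
    "design_matrix",
]

_CONDITION_LIMIT = 1e10


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA decomposition of a fitted regression."""

    df_regression: int
    df_residual: int
    ss_regression: float
    ss_residual: float
    f_stat: float
    p_value: float

    @property
    def df_total(self) -> int:
        return self.df_regression + self.df_residual

    @property
    def ss_total(self) -> float:
        return self.ss_regression + self.ss_residual

    @property
    def ms_regression(self) -> float:
        return self.ss_regression / self.df_regression

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    @property
    def r2(self) -> float:
        return self.ss_regression / self.ss_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_regression, self.df_residual, self.df_total],
                "SS": [self.ss_regression, self.ss_residual, self.ss_total],
                "MS": [self.ms_regression, self.ms_residual, np.nan],
                "F": [self.f_stat, np.nan, np.nan],
                "p_value": [self.p_value, np.nan, np.nan],
            },
            index=["Regression", "Residual", "Total"],
        )


@dataclass(frozen=True)
class FitSummary:
    r2: float
    r2_adj: float
    fitted: pd.Series
    standardized_residuals: pd.Series


def design_matrix(X: DescriptorTable, model: LinearModel | None = None) -> np.ndarray:
    """Intercept-augmented design matrix (leading column of ones)."""
    values = X.select(model.descriptor_names).values if model is not None else X.values
    return np.column_stack([np.ones(values.shape[0]), values])


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    # condition number on unit-scaled columns; a huge value means some
    # column is (numerically) a linear combination of the others
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    cond = np.linalg.cond(A / norms)
    if not np.isfinite(cond) or cond > _CONDITION_LIMIT:
        _, s, vt = np.linalg.svd(A / norms)
        null_mask = np.abs(vt[-1]) > 1e-6
        involved = [(["<intercept>"] + names)[k] for k in np.flatnonzero(null_mask)]
        raise SingularityError(
            f"design matrix is rank deficient (cond={cond:.3g}); "
            f"dependent columns: {involved}"
        )


def _align(X: DescriptorTable, y: ActivitySeries) -> np.ndarray:
    return y.reindex(X.compound_ids).values


def fit_ols(X: DescriptorTable, y: ActivitySeries) -> LinearModel:
    """Least-squares fit of pIC50 on the table's descriptor columns."""
    n, p = X.shape
    if n <= p + 1:
        raise DomainError(f"need n > p + 1 observations (n={n}, p={p})")
    A = design_matrix(X)
    _check_rank(A, X.descriptor_names)
    beta, *_ = np.linalg.lstsq(A, _align(X, y), rcond=None)
    return LinearModel(
        descriptor_names=tuple(X.descriptor_names),
        coefficients=tuple(beta[1:]),
        intercept=float(beta[0]),
    )


def anova(model: LinearModel, X: DescriptorTable, y: ActivitySeries) -> AnovaTable:
    """ANOVA decomposition about the mean for a fitted model."""
    yv = _align(X, y)
    fitted = model.predict(X).values
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_res <= 1e-12 * max(ss_tot, 1.0):  # numerically perfect fit
        ss_res = 0.0
    ss_reg = ss_tot - ss_res
    return anova_from_sums(ss_reg, model.n_descriptors, ss_res, len(yv) - model.n_descriptors - 1)


def anova_from_sums(
    ss_regression: float, df_regression: int, ss_residual: float, df_residual: int
) -> AnovaTable:
    """Assemble the ANOVA table (F, p) from sums of squares and dfs."""
    if df_regression < 1 or df_residual < 1:
        raise DomainError("degrees of freedom must be >= 1")
    ms_reg = ss_regression / df_regression
    ms_res = ss_residual / df_residual
    if ms_res <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ms_reg / ms_res
        p_value = float(stats.f.sf(f_stat, df_regression, df_residual))
    return AnovaTable(
        df_regression=df_regression,
        df_residual=df_residual,
        ss_regression=float(ss_regression),
        ss_residual=float(ss_residual),
        f_stat=float(f_stat),
        p_value=p_value,
    )


def r2_adjusted(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise DomainError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def standardized_residuals(model: LinearModel, X: DescriptorTable, y: ActivitySeries) -> pd.Series:
    """Residuals divided by s = sqrt(SS_res / df_residual)."""
    yv = _align(X, y)
    resid = yv - model.predict(X).values
    df_res = len(yv) - model.n_descriptors - 1
    if df_res < 1:
        raise DomainError("no residual degrees of freedom")
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_res <= 1e-12 * max(ss_tot, 1.0):  # numerically perfect fit
        return pd.Series(np.zeros_like(resid), index=X.compound_ids, name="std_residual")
    s = np.sqrt(ss_res / df_res)
    return pd.Series(resid / s, index=X.compound_ids, name="std_residual")


def fit_summary(model: LinearModel, X: DescriptorTable, y: ActivitySeries) -> FitSummary:
    table = anova(model, X, y)
    n = X.shape[0]
    return FitSummary(
        r2=table.r2,
        r2_adj=r2_adjusted(table.r2, n, model.n_descriptors),
        fitted=model.predict(X).series,
        standardized_residuals=standardized_residuals(model, X, y),
    )


def coefficient_table(model: LinearModel, X: DescriptorTable, y: ActivitySeries) -> pd.DataFrame:
    """Per-coefficient standard errors and two-sided t-tests.

    SE comes from the usual OLS covariance s^2 (A'A)^-1; the intercept
    row is included first under the label ``<intercept>``.
    """
    A = design_matrix(X, model)
    yv = _align(X, y)
    n, k = A.shape
    if n <= k:
        raise DomainError("no residual degrees of freedom for coefficient tests")
    resid = yv - model.predict(X).values
    df_res = n - k
    s2 = float(np.sum(resid**2)) / df_res
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    coefs = np.concatenate([[model.intercept], model.coefficients])
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, coefs / se, np.inf * np.sign(coefs))
    p = 2.0 * stats.t.sf(np.abs(t), df_res)
    return pd.DataFrame(
        {"coefficient": coefs, "std_error": se, "t_stat": t, "p_value": p},
        index=["<intercept>"] + list(model.descriptor_names),
    )
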