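"""Internal and external validation metrics and the benchmark gate.

A candidate regression model is accepted only if it clears the standard
benchmark thresholds: R^2 >= 0.6, adjusted R^2 >= 0.6, leave-one-out
Q^2 >= 0.5 and external R^2 >= 0.6 (all inclusive).

Metric definitions
------------------
Q^2 (LOO)    1 - PRESS / SS_total, PRESS summing squared leave-one-out
             prediction errors.  Computed through the exact hat-matrix
             identity e_i / (1 - h_ii); no refitting loop.
R^2_ext      1 - sum (y_exp - y_pred)^2 / sum (y_exp - ybar_train)^2
             over the test set, centred on the *training* mean.
VIF          leading diagonal of the inverse of the Pearson correlation
             matrix of the model's descriptor columns.
Mean effect  ME_j = beta_j * sum_i x_ij / sum_k beta_k * sum_i x_ik,
             a signed fraction of the total descriptor contribution to
             the predicted activity; the values sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivitySeries, DescriptorTable, DomainError, LinearModel, SingularityError
from .mlr import design_matrix, fit_ols, r2_adjusted, anova, coefficient_table

__all__ = [
    "BenchmarkVerdict",
    "Criterion",
    "q2_loo",
    "r2_external",
    "vif",
    "mean_effect",
    "descriptor_diagnostics",
    "benchmark_gate",
    "DEFAULT_BENCHMARKS",
    "DEFAULT_VIF_ALARM",
]

#: inclusive lower bounds a significant model must reach
DEFAULT_BENCHMARKS = {"r2": 0.6, "r2_adj": 0.6, "q2_cv": 0.5, "r2_ext": 0.6}

#: VIF above this value flags a collinear descriptor pair
DEFAULT_VIF_ALARM = 4.0


@dataclass(frozen=True)
class Criterion:
    name: str
    value: float
    threshold: float

    @property
    def passed(self) -> bool:
        return bool(self.value >= self.threshold)


@dataclass(frozen=True)
class BenchmarkVerdict:
    criteria: tuple[Criterion, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.criteria)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, c.value, c.threshold, c.passed) for c in self.criteria],
            columns=["criterion", "value", "threshold", "passed"],
        )


def q2_loo(X: DescriptorTable, y: ActivitySeries) -> float:
    """Leave-one-out cross-validated R^2 (1 - PRESS/SS_total)."""
    model = fit_ols(X, y)
    A = design_matrix(X)
    yv = y.reindex(X.compound_ids).values
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("constant response: Q^2 undefined")
    h = np.einsum("ij,ij->i", A, np.linalg.solve(A.T @ A, A.T).T)
    near_one = h > 1 - 1e-10
    if near_one.any():
        who = [X.compound_ids[k] for k in np.flatnonzero(near_one)]
        raise SingularityError(f"leave-one-out fit rank deficient when omitting {who}")
    resid = yv - model.predict(X).values
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    return 1.0 - press / ss_tot


def r2_external(y_exp_test, y_pred_test, ybar_train: float) -> float:
    """External coefficient of determination, centred on the training mean."""
    y_exp = np.asarray(
        y_exp_test.values if isinstance(y_exp_test, ActivitySeries) else y_exp_test, float
    )
    y_pred = np.asarray(
        y_pred_test.values if isinstance(y_pred_test, ActivitySeries) else y_pred_test, float
    )
    if y_exp.size == 0:
        raise DomainError("empty test set")
    if y_exp.shape != y_pred.shape:
        raise DomainError("experimental/predicted length mismatch")
    denom = float(np.sum((y_exp - ybar_train) ** 2))
    if denom == 0:
        raise DomainError("test activities all equal the training mean")
    return 1.0 - float(np.sum((y_exp - y_pred) ** 2)) / denom


def vif(X_model: DescriptorTable) -> pd.Series:
    """Variance inflation factors of the model's descriptor columns."""
    n, p = X_model.shape
    if p < 2:
        raise DomainError("VIF needs at least two descriptors")
    values = X_model.values
    if np.any(values.std(axis=0) == 0):
        raise DomainError("constant descriptor column")
    corr = np.corrcoef(values, rowvar=False)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise SingularityError("singular correlation matrix (perfect collinearity)") from exc
    if np.linalg.cond(corr) > 1e12:
        raise SingularityError("correlation matrix numerically singular")
    return pd.Series(np.diag(inv), index=X_model.descriptor_names, name="VIF")


def mean_effect(model: LinearModel, X_train: DescriptorTable) -> pd.Series:
    """Signed fractional contribution of each descriptor (sums to 1)."""
    cols = X_train.select(model.descriptor_names).values
    weighted = np.asarray(model.coefficients) * cols.sum(axis=0)
    total = weighted.sum()
    if total == 0:
        raise DomainError("total descriptor contribution is zero")
    return pd.Series(weighted / total, index=model.descriptor_names, name="ME")


def descriptor_diagnostics(
    model: LinearModel, X_train: DescriptorTable, y_train: ActivitySeries
) -> pd.DataFrame:
    """Per-descriptor table: coefficient, ME, VIF, t, p, SE."""
    X = X_train.select(model.descriptor_names)
    coefs = coefficient_table(model, X, y_train).drop(index="<intercept>")
    vifs = (
        vif(X)
        if model.n_descriptors >= 2
        else pd.Series(1.0, index=model.descriptor_names, name="VIF")
    )
    return pd.DataFrame(
        {
            "coefficient": coefs["coefficient"],
            "ME": mean_effect(model, X),
            "VIF": vifs,
            "t_stat": coefs["t_stat"],
            "p_value": coefs["p_value"],
            "SE": coefs["std_error"],
        }
    )


def benchmark_gate(
    r2: float,
    r2_adj: float,
    q2_cv: float,
    r2_ext: float,
    thresholds: dict[str, float] | None = None,
) -> BenchmarkVerdict:
    """Check the four fit metrics against their benchmark thresholds."""
    limits = dict(DEFAULT_BENCHMARKS)
    if thresholds:
        limits.update(thresholds)
    values = {"r2": r2, "r2_adj": r2_adj, "q2_cv": q2_cv, "r2_ext": r2_ext}
    return BenchmarkVerdict(
        criteria=tuple(Criterion(name, float(values[name]), float(limits[name])) for name in values)
    )


def validate_model(
    model: LinearModel,
    X_train: DescriptorTable,
    y_train: ActivitySeries,
    X_test: DescriptorTable,
    y_test: ActivitySeries,
    thresholds: dict[str, float] | None = None,
) -> dict:
    """Convenience wrapper producing the full validation report.

    Returns a dict with the ANOVA table, the four gate metrics, the
    verdict, and the per-descriptor diagnostics frame.
    """
    Xm = X_train.select(model.descriptor_names)
    table = anova(model, Xm, y_train)
    r2 = table.r2
    r2a = r2_adjusted(r2, Xm.shape[0], model.n_descriptors)
    q2 = q2_loo(Xm, y_train)
    ybar = float(y_train.values.mean())
    r2e = r2_external(y_test, model.predict(X_test), ybar)
    return {
        "anova": table,
        "metrics": {"r2": r2, "r2_adj": r2a, "q2_cv": q2, "r2_ext": r2e},
        "verdict": benchmark_gate(r2, r2a, q2, r2e, thresholds),
        "diagnostics": descriptor_diagnostics(model, X_train, y_train),
    }
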