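"""Leverage-based applicability domain (Williams plot data).

A prediction is trusted only for compounds structurally similar to the
training set.  Similarity is measured by the leverage

    h = x (X'X)^-1 x'

with intercept-augmented rows and X the training design matrix.  The
warning leverage is h* = 3 (p + 1) / n and the residual band is +/- 3
standardized units; a compound is inside the domain iff h <= h* and its
standardized residual (on the training residual scale) lies within the
band.  Training self-leverages lie in [0, 1] and sum to p + 1; query
leverages are unbounded above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivitySeries, DescriptorTable, DomainError, LinearModel, QSARDataset
from .mlr import design_matrix

__all__ = ["ADResult", "leverages", "warning_leverage", "williams"]

DEFAULT_RESIDUAL_BAND = 3.0


@dataclass(frozen=True)
class ADResult:
    """Williams-plot data: per-compound (h, std residual, inside flag)."""

    records: pd.DataFrame  # columns: leverage, std_residual, membership, inside_domain
    h_star: float
    residual_band: float

    def outside(self) -> list[str]:
        return self.records.index[~self.records["inside_domain"]].tolist()


def warning_leverage(n_train: int, p: int) -> float:
    """h* = 3 (p + 1) / n."""
    if n_train < 1:
        raise DomainError("empty training set")
    return 3.0 * (p + 1) / n_train


def leverages(X_train: DescriptorTable, X_query: DescriptorTable | None = None) -> pd.Series:
    """Leverage of each query row w.r.t. the training design matrix.

    With ``X_query=None`` returns the training self-leverages (the hat
    matrix diagonal).
    """
    if X_query is None:
        X_query = X_train
    missing = [c for c in X_train.descriptor_names if c not in X_query.descriptor_names]
    if missing:
        raise DomainError(f"query table lacks training descriptors: {missing}")
    A = design_matrix(X_train)
    xtx = A.T @ A
    if np.linalg.cond(xtx) > 1e12:
        raise DomainError("training design matrix numerically rank deficient")
    Q = np.column_stack(
        [np.ones(X_query.shape[0]), X_query.select(X_train.descriptor_names).values]
    )
    h = np.einsum("ij,ij->i", Q, np.linalg.solve(xtx, Q.T).T)
    return pd.Series(h, index=X_query.compound_ids, name="leverage")


def williams(
    model: LinearModel,
    train: QSARDataset | tuple[DescriptorTable, ActivitySeries],
    query: QSARDataset | tuple[DescriptorTable, ActivitySeries] | None = None,
    residual_band: float = DEFAULT_RESIDUAL_BAND,
) -> ADResult:
    """Applicability-domain assessment of training and query compounds.

    Query standardized residuals use the *training* residual scale
    s = sqrt(SS_res / df_residual), so all compounds share one band.
    """
    X_tr, y_tr = train.train() if isinstance(train, QSARDataset) else train
    X_tr = X_tr.select(model.descriptor_names)
    n, p = X_tr.shape
    h_star = warning_leverage(n, p)

    resid_tr = y_tr.reindex(X_tr.compound_ids).values - model.predict(X_tr).values
    df_res = n - p - 1
    if df_res < 1:
        raise DomainError("no residual degrees of freedom in training fit")
    s = float(np.sqrt(np.sum(resid_tr**2) / df_res))

    blocks = [(X_tr, resid_tr, "train")]
    if query is not None:
        X_q, y_q = query.test() if isinstance(query, QSARDataset) else query
        resid_q = y_q.reindex(X_q.compound_ids).values - model.predict(X_q).values
        blocks.append((X_q, resid_q, "query"))

    frames = []
    for X_blk, resid, label in blocks:
        h = leverages(X_tr, X_blk)
        std = resid / s if s > 0 else np.zeros_like(resid)
        frames.append(
            pd.DataFrame(
                {
                    "leverage": h,
                    "std_residual": std,
                    "membership": label,
                },
                index=X_blk.compound_ids,
            )
        )
    records = pd.concat(frames)
    records["inside_domain"] = (records["leverage"] <= h_star) & (
        records["std_residual"].abs() <= residual_band
    )
    return ADResult(records=records, h_star=h_star, residual_band=residual_band)
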