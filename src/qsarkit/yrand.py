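"""Y-randomization: refit under scrambled response to establish a chance baseline.

The response vector is permuted (Fisher-Yates, seeded) while the
descriptor matrix stays fixed, the model is refit by OLS, and R, R^2 and
leave-one-out Q^2 of each random refit are recorded.  Permuting the
response rows is equivalent, for every OLS statistic, to permuting the
descriptor rows against a fixed response, and is the cheaper bookkeeping.

A robust model keeps its original R^2 and Q^2 well above the random
averages, and its robustness coefficient

    cRp^2 = R * sqrt(R^2 - Rr_bar^2)

(where Rr_bar is the arithmetic mean of the random-model R values)
stays above 0.5.  A negative radicand means the random models come too
close to the original; NaN is returned to flag the model as not robust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ActivitySeries, DescriptorTable, DomainError
from .mlr import anova, fit_ols
from .validation import q2_loo

__all__ = ["YRandResult", "y_randomize", "c_rp2"]


@dataclass(frozen=True)
class YRandResult:
    """Original and per-permutation (R, R^2, Q^2) records plus cRp^2."""

    original: tuple[float, float, float]
    randoms: tuple[tuple[float, float, float], ...]
    c_rp2: float

    @property
    def avg_r(self) -> float:
        return float(np.mean([r for r, _, _ in self.randoms]))

    @property
    def avg_r2(self) -> float:
        return float(np.mean([r2 for _, r2, _ in self.randoms]))

    @property
    def avg_q2(self) -> float:
        return float(np.mean([q2 for _, _, q2 in self.randoms]))

    def to_frame(self) -> pd.DataFrame:
        rows = [("original", *self.original)]
        rows += [(f"random_{k + 1}", *rec) for k, rec in enumerate(self.randoms)]
        return pd.DataFrame(rows, columns=["model", "R", "R2", "Q2"]).set_index("model")


def c_rp2(r_original: float, r2_original: float, random_rs) -> float:
    """Robustness coefficient R * sqrt(R^2 - (mean random R)^2).

    Returns NaN when the radicand is negative (model not distinguishable
    from its permutation null).
    """
    rs = np.asarray(list(random_rs), dtype=float)
    if rs.size == 0:
        raise DomainError("need at least one random-model R value")
    radicand = r2_original - float(rs.mean()) ** 2
    if radicand < 0:
        return math.nan
    return float(r_original * math.sqrt(radicand))


def _r_r2_q2(X: DescriptorTable, y: ActivitySeries) -> tuple[float, float, float]:
    model = fit_ols(X, y)
    r2 = anova(model, X, y).r2
    # for an intercept OLS fit corr(fitted, observed) >= 0, so R = +sqrt(R^2)
    return math.sqrt(max(r2, 0.0)), r2, q2_loo(X, y)


def y_randomize(
    X: DescriptorTable, y: ActivitySeries, n_permutations: int = 10, seed: int = 0
) -> YRandResult:
    """Fit the original model and ``n_permutations`` scrambled-response refits."""
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    original = _r_r2_q2(X, y)
    yv = y.reindex(X.compound_ids).values
    ids = X.compound_ids
    randoms = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(yv))
        y_perm = ActivitySeries.from_values(ids, yv[perm])
        randoms.append(_r_r2_q2(X, y_perm))
    coeff = c_rp2(original[0], original[1], [r for r, _, _ in randoms])
    return YRandResult(original=original, randoms=tuple(randoms), c_rp2=coeff)
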