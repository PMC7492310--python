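"""Descriptor pretreatment: drop constant and inter-correlated columns.

Large descriptor pools carry many redundant columns; before data
division they are pruned in two passes:

1. columns with (sample) variance at or below a tolerance are removed;
2. a greedy left-to-right scan keeps a column only if its absolute
   Pearson correlation with every already-kept column is <= the cutoff
   (default 0.7).  First-seen wins, which makes the result deterministic
   and order-documented.

Values exactly at the cutoff survive: a column is dropped only when
|r| strictly exceeds the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DescriptorTable, DomainError

__all__ = ["PretreatReport", "remove_constant", "correlation_filter", "pretreat"]

DEFAULT_CUTOFF = 0.7
DEFAULT_VARIANCE_TOL = 1e-8


@dataclass
class PretreatReport:
    """Audit trail of a pretreatment pass.

    ``dropped_correlated`` records, for each removed column, the kept
    column that triggered the removal and the offending |r|.
    """

    dropped_constant: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return self.dropped_constant + [name for name, _, _ in self.dropped_correlated]

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, "constant", "", np.nan) for name in self.dropped_constant]
        rows += [(name, "correlated", kept, r) for name, kept, r in self.dropped_correlated]
        rows += [(name, "kept", "", np.nan) for name in self.survivors]
        return pd.DataFrame(rows, columns=["descriptor", "status", "conflicts_with", "abs_r"])

    @staticmethod
    def merge(first: "PretreatReport", second: "PretreatReport") -> "PretreatReport":
        return PretreatReport(
            dropped_constant=first.dropped_constant + second.dropped_constant,
            dropped_correlated=first.dropped_correlated + second.dropped_correlated,
            survivors=second.survivors,
        )


def remove_constant(
    table: DescriptorTable, variance_tol: float = DEFAULT_VARIANCE_TOL
) -> tuple[DescriptorTable, PretreatReport]:
    """Drop every column whose sample variance is <= ``variance_tol``."""
    if variance_tol < 0:
        raise DomainError("variance_tol must be >= 0")
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise DomainError("empty descriptor table")
    variances = table.frame.var(axis=0, ddof=1).to_numpy()
    keep = variances > variance_tol
    names = np.asarray(table.descriptor_names)
    report = PretreatReport(
        dropped_constant=names[~keep].tolist(),
        survivors=names[keep].tolist(),
    )
    if not keep.any():
        warnings.warn("all descriptor columns are (near-)constant", stacklevel=2)
    return table.select(report.survivors), report


def correlation_filter(
    table: DescriptorTable, cutoff: float = DEFAULT_CUTOFF
) -> tuple[DescriptorTable, PretreatReport]:
    """Greedy scan keeping columns with pairwise |Pearson r| <= cutoff.

    Assumes constant columns were already removed (correlations with a
    constant column are undefined).
    """
    if not (0 < cutoff <= 1):
        raise DomainError(f"cutoff must lie in (0, 1], got {cutoff}")
    values = table.values
    if np.any(values.std(axis=0) == 0):
        raise DomainError("constant columns present; run remove_constant first")
    names = table.descriptor_names
    corr = np.corrcoef(values, rowvar=False)
    if corr.ndim == 0:  # single column
        corr = np.ones((1, 1))
    kept: list[int] = []
    report = PretreatReport()
    # |r| exactly at the cutoff survives; the epsilon keeps float round-off
    # in corrcoef from flipping that boundary decision
    eps = 1e-12
    for j in range(len(names)):
        offending = [k for k in kept if abs(corr[j, k]) > cutoff + eps]
        if offending:
            k = offending[0]
            report.dropped_correlated.append((names[j], names[k], float(abs(corr[j, k]))))
        else:
            kept.append(j)
    report.survivors = [names[j] for j in kept]
    return table.select(report.survivors), report


def pretreat(
    table: DescriptorTable,
    cutoff: float = DEFAULT_CUTOFF,
    variance_tol: float = DEFAULT_VARIANCE_TOL,
) -> tuple[DescriptorTable, PretreatReport]:
    """Full pretreatment: constant removal then correlation filtering."""
    reduced, rep1 = remove_constant(table, variance_tol)
    if reduced.shape[1] == 0:
        return reduced, rep1
    final, rep2 = correlation_filter(reduced, cutoff)
    return final, PretreatReport.merge(rep1, rep2)
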