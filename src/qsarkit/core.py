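"""Core domain types and activity-scale transforms.

The package models cytotoxic potency on the pIC50 scale, the negative
base-10 logarithm of the molar IC50.  Assay tables report IC50 in
micromolar, so the two scales are linked by

    pIC50 = 6 - log10(IC50 [uM])        IC50 [uM] = 10 ** (6 - pIC50)

Concentrations cross every API boundary in micromolar; the factor of 6
(log10 of 1e6) is applied internally and never exposed.

Three containers carry the data through the pipeline:

* :class:`DescriptorTable` -- a compound-by-descriptor matrix of finite
  numeric molecular descriptors (e.g. PaDEL output).
* :class:`ActivitySeries`  -- per-compound pIC50 values.
* :class:`QSARDataset`     -- the two joined by compound id, plus an
  optional train/test membership label.

:class:`LinearModel` holds a fitted (or published) multilinear regression
equation as named coefficients plus an intercept, and predicts by joining
on descriptor *names*, never column positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QSARError",
    "LoadError",
    "DomainError",
    "SingularityError",
    "DescriptorTable",
    "ActivitySeries",
    "QSARDataset",
    "LinearModel",
    "TRAIN",
    "TEST",
    "UNASSIGNED",
    "pic50_from_ic50_uM",
    "ic50_uM_from_pic50",
]


class QSARError(Exception):
    """Base class for all errors raised by this package."""


class LoadError(QSARError):
    """A file or document could not be parsed into a valid domain object."""


class DomainError(QSARError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SingularityError(QSARError):
    """A design or correlation matrix is (numerically) rank deficient."""


TRAIN = "train"
TEST = "test"
UNASSIGNED = "unassigned"

# pIC50 is -log10 of a molar concentration; micromolar inputs shift by log10(1e6)
_UM_TO_M_LOG = 6.0


def pic50_from_ic50_uM(ic50):
    """Convert IC50 in micromolar to pIC50 (-log10 molar).

    Accepts a scalar or array; strictly decreasing in its argument.
    Raises :class:`DomainError` for non-positive or non-finite input.
    """
    arr = np.asarray(ic50, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("IC50 must be finite and > 0 (in uM)")
    out = _UM_TO_M_LOG - np.log10(arr)
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def ic50_uM_from_pic50(pic50):
    """Convert pIC50 (-log10 molar) back to IC50 in micromolar.

    Exact inverse of :func:`pic50_from_ic50_uM`.
    """
    arr = np.asarray(pic50, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("pIC50 must be finite")
    out = np.power(10.0, _UM_TO_M_LOG - arr)
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()
        raise LoadError(f"duplicate {what}: {dupes}")


class DescriptorTable:
    """Immutable compound-by-descriptor matrix.

    Rows are compounds (unique text ids), columns are named molecular
    descriptors; every cell must be a finite real number.  Column order
    is meaningful and preserved by all operations.
    """

    def __init__(self, frame: pd.DataFrame):
        _check_unique(frame.index, "compound ids")
        _check_unique(frame.columns, "descriptor names")
        try:
            values = frame.astype(float)
        except (TypeError, ValueError) as exc:
            raise LoadError(f"non-numeric descriptor values: {exc}") from exc
        bad = ~np.isfinite(values.to_numpy())
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise LoadError(
                f"non-finite value for descriptor {values.columns[j]!r} "
                f"of compound {values.index[i]!r}"
            )
        self._frame = values
        self._frame.index = self._frame.index.astype(str).rename("Name")
        self._frame.columns = self._frame.columns.astype(str)

    @classmethod
    def from_arrays(
        cls,
        compound_ids: Sequence[str],
        descriptor_names: Sequence[str],
        values,
    ) -> "DescriptorTable":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(compound_ids),
                                columns=list(descriptor_names)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def compound_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def descriptor_names(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy(copy=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def select(self, names: Iterable[str]) -> "DescriptorTable":
        """Column subset in the given order; unknown names raise."""
        names = list(names)
        missing = [n for n in names if n not in self._frame.columns]
        if missing:
            raise DomainError(f"unknown descriptors: {missing}")
        return DescriptorTable(self._frame[names])

    def subset(self, compound_ids: Iterable[str]) -> "DescriptorTable":
        """Row subset in the given order; unknown ids raise."""
        ids = list(compound_ids)
        missing = [i for i in ids if i not in self._frame.index]
        if missing:
            raise DomainError(f"unknown compounds: {missing}")
        return DescriptorTable(self._frame.loc[ids])

    def equals(self, other: "DescriptorTable") -> bool:
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        n, p = self.shape
        return f"DescriptorTable({n} compounds x {p} descriptors)"


class ActivitySeries:
    """Per-compound pIC50 values (-log10 molar), indexed by compound id."""

    def __init__(self, series: pd.Series):
        _check_unique(series.index, "compound ids")
        vals = series.astype(float)
        if not np.all(np.isfinite(vals.to_numpy())):
            bad = vals.index[~np.isfinite(vals.to_numpy())].tolist()
            raise LoadError(f"non-finite activity for compounds {bad}")
        self._series = vals.rename("pIC50")
        self._series.index = self._series.index.astype(str).rename("Name")

    @classmethod
    def from_values(cls, compound_ids: Sequence[str], pic50) -> "ActivitySeries":
        return cls(pd.Series(np.asarray(pic50, dtype=float), index=list(compound_ids)))

    @classmethod
    def from_ic50_uM(cls, compound_ids: Sequence[str], ic50_uM) -> "ActivitySeries":
        return cls.from_values(compound_ids, pic50_from_ic50_uM(np.asarray(ic50_uM, float)))

    @property
    def series(self) -> pd.Series:
        return self._series.copy()

    @property
    def compound_ids(self) -> list[str]:
        return self._series.index.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._series.to_numpy(copy=True)

    def reindex(self, compound_ids: Iterable[str]) -> "ActivitySeries":
        ids = list(compound_ids)
        missing = [i for i in ids if i not in self._series.index]
        if missing:
            raise DomainError(f"no activity for compounds {missing}")
        return ActivitySeries(self._series.loc[ids])

    def __len__(self) -> int:
        return len(self._series)

    def __repr__(self) -> str:
        return f"ActivitySeries({len(self)} compounds)"


class QSARDataset:
    """Descriptor table + activity joined by compound id.

    The activity is re-aligned to the table's row order at construction
    (the join is order-insensitive), and both must cover identical id
    sets.  ``membership`` labels each compound train/test/unassigned.
    """

    def __init__(
        self,
        table: DescriptorTable,
        activity: ActivitySeries,
        membership: Mapping[str, str] | pd.Series | None = None,
    ):
        if set(table.compound_ids) != set(activity.compound_ids):
            only_t = sorted(set(table.compound_ids) - set(activity.compound_ids))
            only_a = sorted(set(activity.compound_ids) - set(table.compound_ids))
            raise DomainError(
                f"table/activity id mismatch (table-only {only_t}, activity-only {only_a})"
            )
        self.table = table
        self.activity = activity.reindex(table.compound_ids)
        if membership is None:
            member = pd.Series(UNASSIGNED, index=table.compound_ids)
        else:
            member = pd.Series(membership).reindex(table.compound_ids).fillna(UNASSIGNED)
        bad = sorted(set(member) - {TRAIN, TEST, UNASSIGNED})
        if bad:
            raise DomainError(f"invalid membership labels: {bad}")
        self.membership = member.astype(str).rename("membership")
        self.membership.index = self.membership.index.rename("Name")

    @property
    def compound_ids(self) -> list[str]:
        return self.table.compound_ids

    def _labelled(self, label: str) -> tuple[DescriptorTable, ActivitySeries]:
        ids = self.membership.index[self.membership == label].tolist()
        if not ids:
            raise DomainError(f"no compounds labelled {label!r}")
        return self.table.subset(ids), self.activity.reindex(ids)

    def train(self) -> tuple[DescriptorTable, ActivitySeries]:
        return self._labelled(TRAIN)

    def test(self) -> tuple[DescriptorTable, ActivitySeries]:
        return self._labelled(TEST)

    def with_membership(self, train_ids: Iterable[str], test_ids: Iterable[str]) -> "QSARDataset":
        member = pd.Series(UNASSIGNED, index=self.table.compound_ids)
        member.loc[list(train_ids)] = TRAIN
        member.loc[list(test_ids)] = TEST
        return QSARDataset(self.table, self.activity, member)

    def __repr__(self) -> str:
        counts = self.membership.value_counts().to_dict()
        return f"QSARDataset({self.table!r}, membership={counts})"


@dataclass(frozen=True)
class LinearModel:
    """A multilinear regression equation: pIC50 = intercept + sum(beta_j * x_j).

    Coefficients are bound to descriptor *names*; prediction joins by
    name, so candidate tables may carry extra columns in any order.
    """

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.descriptor_names) != len(self.coefficients):
            raise DomainError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.descriptor_names)} descriptor names"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise DomainError("duplicate descriptor names in model")
        object.__setattr__(self, "descriptor_names", tuple(str(n) for n in self.descriptor_names))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "intercept", float(self.intercept))

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def coefficient(self, name: str) -> float:
        try:
            return self.coefficients[self.descriptor_names.index(name)]
        except ValueError:
            raise DomainError(f"model has no descriptor {name!r}") from None

    def predict(self, rows: DescriptorTable) -> ActivitySeries:
        """Predicted pIC50 for every compound in ``rows``."""
        missing = [n for n in self.descriptor_names if n not in rows.descriptor_names]
        if missing:
            raise DomainError(f"candidate table lacks model descriptors: {missing}")
        X = rows.select(self.descriptor_names).values
        yhat = X @ np.asarray(self.coefficients) + self.intercept
        return ActivitySeries.from_values(rows.compound_ids, yhat)

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.descriptor_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "metadata": dict(self.metadata),
        }
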