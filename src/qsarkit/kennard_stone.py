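"""Kennard-Stone maxmin division into training and test sets.

The algorithm is fully deterministic: the first two training picks are
the pair of compounds at maximal Euclidean distance; every subsequent
pick is the compound whose minimum distance to the already-picked set is
largest.  Compounds never picked form the test set.  Distances are
computed on autoscaled (zero-mean, unit-variance) descriptors so that
large-magnitude columns do not dominate the metric.

Ties (equal distances, including exact duplicate rows) are broken by
the lower row index, preserving determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import DescriptorTable, DomainError

__all__ = ["SplitResult", "ks_split", "train_size"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test id lists; ``selection_order`` is pick order."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    selection_order: tuple[str, ...]

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def train_size(n: int, train_fraction: float) -> int:
    """floor(fraction * n), never below 2 (the seeding pair)."""
    return max(2, int(np.floor(train_fraction * n)))


def ks_split(table: DescriptorTable, train_fraction: float = 0.7) -> SplitResult:
    """Divide ``table`` into training/test sets by the Kennard-Stone rule."""
    if not (0 < train_fraction < 1):
        raise DomainError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = table.shape[0]
    if n < 3:
        raise DomainError(f"need at least 3 compounds to split, got {n}")
    values = table.values
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DomainError("constant descriptor columns; pretreat before splitting")
    scaled = (values - values.mean(axis=0)) / sd

    dist = squareform(pdist(scaled, metric="euclidean"))
    n_train = train_size(n, train_fraction)

    # seed: the most distant pair; np.argmax scans row-major, so the
    # first maximal entry has the lexicographically smallest (i, j)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    picked = [int(min(i, j)), int(max(i, j))]
    remaining = [k for k in range(n) if k not in picked]

    min_dist = np.minimum(dist[picked[0]], dist[picked[1]])
    while len(picked) < n_train:
        cand = remaining[int(np.argmax(min_dist[remaining]))]
        picked.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, dist[cand])

    ids = table.compound_ids
    order = tuple(ids[k] for k in picked)
    return SplitResult(
        train_ids=tuple(ids[k] for k in sorted(picked)),
        test_ids=tuple(ids[k] for k in sorted(remaining)),
        selection_order=order,
    )
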