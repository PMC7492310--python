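"""Genetic function algorithm: descriptor-subset search with Friedman LOF fitness.

Individuals are fixed-length sets of descriptor indices.  Each is scored
by fitting OLS on its columns and computing the Friedman lack-of-fit

    LOF = (SS_res / n) / (1 - (c + d * p) / n)^2

with c the number of model terms including the intercept, p the number
of descriptors and d a smoothness penalty (default 0.5).  Smaller is
better: LOF inflates the mean squared residual as the model grows
relative to the sample, so the search favours parsimonious equations.

The evolutionary loop uses uniform-random initialisation, tournament
selection, single-point crossover on sorted index lists (duplicate genes
repaired with random unused descriptors), per-gene mutation and elitism
of the single best individual, which makes the best LOF non-increasing
across generations.  All randomness flows from one seeded generator, so
a fixed seed reproduces the search exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivitySeries, DescriptorTable, DomainError

__all__ = ["GFAConfig", "GFAModel", "GFAResult", "friedman_lof", "gfa_search"]


@dataclass(frozen=True)
class GFAConfig:
    """Search settings; defaults are conventional GFA values."""

    equation_length: int = 5
    population_size: int = 100
    generations: int = 100
    crossover_prob: float = 0.85
    mutation_prob: float = 0.05
    tournament_size: int = 2
    lof_smoothness: float = 0.5  # d in the LOF denominator
    seed: int = 0

    def __post_init__(self):
        if self.equation_length < 1:
            raise DomainError("equation_length must be >= 1")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise DomainError("probabilities must lie in [0, 1]")
        if self.lof_smoothness <= 0:
            raise DomainError("lof_smoothness must be > 0")
        if self.population_size < 2 or self.generations < 1 or self.tournament_size < 1:
            raise DomainError("population_size >= 2, generations >= 1, tournament_size >= 1")


@dataclass(frozen=True)
class GFAModel:
    descriptors: tuple[str, ...]
    lof: float
    r2: float


@dataclass(frozen=True)
class GFAResult:
    """Deduplicated final population ranked by ascending LOF."""

    models: tuple[GFAModel, ...]
    generation_log: tuple[float, ...] = field(default_factory=tuple)  # best LOF per generation

    @property
    def best(self) -> GFAModel:
        return self.models[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [("+".join(m.descriptors), m.lof, m.r2) for m in self.models],
            columns=["descriptors", "LOF", "R2"],
        )


def friedman_lof(ss_res: float, n: int, n_terms: int, d: float, p_total: int) -> float:
    """Friedman lack-of-fit score (smaller = better)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    shrink = 1.0 - (n_terms + d * p_total) / n
    if shrink <= 0:
        raise DomainError(
            f"model too large for sample: n={n}, terms={n_terms}, d={d}, p={p_total}"
        )
    return (ss_res / n) / shrink**2


class _Evaluator:
    """OLS fitness of descriptor subsets, memoised per subset."""

    def __init__(self, X: np.ndarray, y: np.ndarray, d: float):
        self.X = X
        self.y = y
        self.d = d
        self.n = len(y)
        self.ss_tot = float(np.sum((y - y.mean()) ** 2))
        self._cache: dict[tuple[int, ...], tuple[float, float]] = {}

    def __call__(self, subset: tuple[int, ...]) -> tuple[float, float]:
        hit = self._cache.get(subset)
        if hit is not None:
            return hit
        k = len(subset)
        A = np.column_stack([np.ones(self.n), self.X[:, subset]])
        coef, *_ = np.linalg.lstsq(A, self.y, rcond=None)
        ss_res = float(np.sum((self.y - A @ coef) ** 2))
        lof = friedman_lof(ss_res, self.n, k + 1, self.d, k)
        r2 = 1.0 - ss_res / self.ss_tot if self.ss_tot > 0 else 0.0
        out = (lof, r2)
        self._cache[subset] = out
        return out


def _repair(genes: list[int], m: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Replace duplicate genes with random unused descriptors."""
    unique = list(dict.fromkeys(genes))
    while len(unique) < len(genes):
        pool = np.setdiff1d(np.arange(m), unique)
        unique.append(int(rng.choice(pool)))
    return tuple(sorted(unique))


def gfa_search(X: DescriptorTable, y: ActivitySeries, config: GFAConfig) -> GFAResult:
    """Evolve descriptor subsets on (pretreated, training-only) data."""
    n, m = X.shape
    k = config.equation_length
    if m < k:
        raise DomainError(f"descriptor pool ({m}) smaller than equation_length ({k})")
    if k >= n - 2:
        raise DomainError(f"equation_length must be < n_train - 2 ({k} vs n={n})")

    rng = np.random.default_rng(config.seed)
    evaluate = _Evaluator(X.values, y.reindex(X.compound_ids).values, config.lof_smoothness)

    population = [
        tuple(sorted(rng.choice(m, size=k, replace=False).tolist()))
        for _ in range(config.population_size)
    ]
    log: list[float] = []

    def ranked(pop):
        return sorted(pop, key=lambda s: (evaluate(s)[0], s))

    for _ in range(config.generations):
        ordered = ranked(population)
        elite = ordered[0]
        log.append(evaluate(elite)[0])
        children = [elite]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                rivals = rng.integers(0, config.population_size, size=config.tournament_size)
                parents.append(min((population[i] for i in rivals), key=lambda s: evaluate(s)[0]))
            a, b = parents
            if rng.random() < config.crossover_prob and k > 1:
                cut = int(rng.integers(1, k))
                child = list(a[:cut] + b[cut:])
            else:
                child = list(a)
            for g in range(k):
                if rng.random() < config.mutation_prob:
                    pool = np.setdiff1d(np.arange(m), child)
                    child[g] = int(rng.choice(pool))
            children.append(_repair(child, m, rng))
        population = children

    names = X.descriptor_names
    final = ranked(set(population))
    models = tuple(
        GFAModel(
            descriptors=tuple(names[i] for i in subset),
            lof=evaluate(subset)[0],
            r2=evaluate(subset)[1],
        )
        for subset in final
    )
    log.append(models[0].lof)
    return GFAResult(models=models, generation_log=tuple(log))
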