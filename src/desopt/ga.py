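"""Real-coded genetic algorithm over the actual-unit factor box.

The optimizer maximizes an arbitrary fitness function (typically the
trained network surrogate) on a box of extraction conditions.  Operators
are the conventional real-coded set: tournament selection of size 2,
BLX-alpha blend crossover (alpha = 0.5) applied to a configurable fraction
of offspring, per-gene Gaussian mutation with sigma equal to 10% of the
gene's range, clipping to the bounds, and elitism.  Defaults follow the
published run settings: population 100, crossover fraction 0.8, mutation
rate 0.1, 300 generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ann import MLPParams, forward

__all__ = ["GAConfig", "GAResult", "ga_maximize", "fitness_from_surrogate"]


@dataclass
class GAConfig:
    """Genetic-algorithm settings; ``bounds`` is a (lo, hi) pair per gene."""

    bounds: Sequence[tuple[float, float]]
    population_size: int = 100
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.1
    generations: int = 300
    elite_count: int = 2
    blx_alpha: float = 0.5
    mutation_sigma_frac: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        if not (0.0 <= self.crossover_fraction <= 1.0):
            raise ValueError("crossover_fraction must be in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        lo, hi = self.lo_hi()
        if len(lo) == 0 or np.any(hi <= lo):
            raise ValueError("bounds must be nonempty with high > low per gene")

    def lo_hi(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=float)
        return b[:, 0], b[:, 1]


@dataclass
class GAResult:
    """Best individual found, with per-generation fitness history."""

    best_point: np.ndarray
    best_fitness: float
    history_best: np.ndarray = field(default_factory=lambda: np.empty(0))
    history_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    generations_run: int = 0


def _evaluate(fitness: Callable, pop: np.ndarray) -> np.ndarray:
    vals = np.array([fitness(ind) for ind in pop], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = pop[int(np.argmax(~np.isfinite(vals)))]
        raise ValueError(f"non-finite fitness at point {bad.tolist()}")
    return vals


def ga_maximize(fitness: Callable[[np.ndarray], float], config: GAConfig) -> GAResult:
    """Maximize ``fitness`` over the configured box.

    With ``elite_count >= 1`` the best-so-far fitness trace is
    non-decreasing; a fixed seed gives a bit-identical result.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lo_hi()
    span = hi - lo
    n_genes = len(lo)
    pop_n = config.population_size
    sigma = config.mutation_sigma_frac * span

    pop = rng.uniform(lo, hi, (pop_n, n_genes))
    fit = _evaluate(fitness, pop)

    best_i = int(np.argmax(fit))
    best_point, best_fit = pop[best_i].copy(), float(fit[best_i])
    hist_best, hist_mean = [best_fit], [float(fit.mean())]

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elites = pop[order[: config.elite_count]].copy()

        n_children = pop_n - config.elite_count
        # tournament-2 selection for two parent pools
        def select(k: int) -> np.ndarray:
            a = rng.integers(pop_n, size=k)
            b = rng.integers(pop_n, size=k)
            return pop[np.where(fit[a] >= fit[b], a, b)]

        p1 = select(n_children)
        p2 = select(n_children)
        cross = rng.random(n_children) < config.crossover_fraction
        children = p1.copy()
        if cross.any():
            lo_p = np.minimum(p1[cross], p2[cross])
            hi_p = np.maximum(p1[cross], p2[cross])
            d = hi_p - lo_p
            a = config.blx_alpha
            children[cross] = rng.uniform(lo_p - a * d, hi_p + a * d)
        mut = rng.random(children.shape) < config.mutation_rate
        children = children + mut * rng.normal(0.0, 1.0, children.shape) * sigma
        children = np.clip(children, lo, hi)

        pop = np.vstack([elites, children])
        fit = _evaluate(fitness, pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_point = pop[gen_best].copy()
        hist_best.append(best_fit)
        hist_mean.append(float(fit.mean()))

    return GAResult(
        best_point=best_point,
        best_fitness=best_fit,
        history_best=np.array(hist_best),
        history_mean=np.array(hist_mean),
        generations_run=config.generations,
    )


def fitness_from_surrogate(params: MLPParams) -> Callable[[np.ndarray], float]:
    """Fitness function mapping actual-unit conditions to predicted yield.

    Direct maximization convention: higher predicted yield is fitter.
    """

    def fitness(x_actual: np.ndarray) -> float:
        return forward(params, np.asarray(x_actual, dtype=float))

    return fitness
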