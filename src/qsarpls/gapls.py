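"""Genetic-algorithm descriptor selection wrapped around PLS.

Each chromosome is a binary inclusion vector over the descriptor columns.  A
chromosome's fitness is computed from random-subset cross-validated PLS
predictions through

    fitness = 100 - 100 * [SSE_cv / n] / [SS_y / k],   k = n - 1
            = 100 * (1 - (n - 1)/n * SSE_cv / SS_y)

so perfect CV prediction scores 100, predicting the mean scores 100/n, and
worse-than-mean predictions go negative.  The generational loop uses
fitness-proportional (roulette) selection with a rank fallback when fitness
values are non-positive, double (two-point) crossover, per-bit mutation and
single-individual elitism; it stops at the generation cap or when the
configured fraction of the population shares the elite fitness.

Default configuration: population 64, mutation rate 0.003, at most 100
generations, 20% initial term density, 4 random CV subsets re-randomized each
generation, 80% convergence fraction, double crossover.  ``window_width`` is
carried for configuration completeness but is inert (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ActivityVector
from .descriptors import DescriptorMatrix
from .regression import RegressionModel, cv_predictions, fit_pls

__all__ = ["GAConfig", "GAResult", "fitness", "initialize", "evolve"]

EMPTY_FITNESS = -np.inf


@dataclass(frozen=True)
class GAConfig:
    population: int = 64
    mutation_rate: float = 0.003
    max_generations: int = 100
    initial_term_fraction: float = 0.2
    crossover: str = "double"  # "double" (two-point) | "single"
    convergence_fraction: float = 0.8
    n_subsets: int = 4
    window_width: int = 2  # documented, inert
    max_lv: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population % 2:
            raise ValueError("population size must be even")
        for name in ("mutation_rate", "initial_term_fraction", "convergence_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.crossover not in ("double", "single"):
            raise ValueError("crossover must be 'double' or 'single'")


@dataclass
class GAResult:
    best_chromosome: np.ndarray  # bool vector
    best_names: list[str]
    best_fitness: float
    history: list[dict]  # per generation: best/mean fitness, bits on
    model: RegressionModel


def _subset_folds(n: int, n_subsets: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, n_subsets)]


def fitness(
    chrom: np.ndarray,
    A: np.ndarray,
    yv: np.ndarray,
    folds,
    max_lv: int = 10,
) -> tuple[float, int]:
    """CV fitness of one chromosome; returns (fitness, chosen LV count).

    The LV count is the inner-RMSECV argmin over 1..min(max_lv, bits on); the
    fitness is then computed from that LV's cross-validated predictions.
    Empty chromosomes score -inf and are never selected.
    """
    chrom = np.asarray(chrom, dtype=bool)
    bits = int(chrom.sum())
    if bits == 0:
        return EMPTY_FITNESS, 0
    sub = A[:, chrom]
    n = len(yv)
    lv_cap = min(max_lv, bits, n - max(len(f) for f in folds) - 1)
    lv_cap = max(lv_cap, 1)
    preds = cv_predictions(sub, yv, lv_cap, folds)
    sse = np.sum((preds - yv) ** 2, axis=1)
    best_lv = int(np.argmin(sse)) + 1
    ss_y = float(np.sum((yv - yv.mean()) ** 2))
    fit = 100.0 * (1.0 - (n - 1) / n * float(sse[best_lv - 1]) / ss_y)
    return fit, best_lv


def initialize(config: GAConfig, n_descriptors: int, rng: np.random.Generator) -> np.ndarray:
    """Random initial population; each bit on with the initial-term probability,
    empty chromosomes redrawn."""
    pop = rng.random((config.population, n_descriptors)) < config.initial_term_fraction
    for k in range(config.population):
        while not pop[k].any():
            pop[k] = rng.random(n_descriptors) < max(
                config.initial_term_fraction, 1.0 / n_descriptors
            )
    return pop


def _crossover(a: np.ndarray, b: np.ndarray, kind: str, rng: np.random.Generator):
    n = a.size
    child1, child2 = a.copy(), b.copy()
    if n < 2:
        return child1, child2
    if kind == "double":
        i, j = sorted(rng.choice(n, size=2, replace=False))
        child1[i:j], child2[i:j] = b[i:j], a[i:j]
    else:  # single point
        i = int(rng.integers(1, n))
        child1[i:], child2[i:] = b[i:], a[i:]
    return child1, child2


def _select_parents(pop: np.ndarray, fits: np.ndarray, rng: np.random.Generator):
    """Roulette on shifted fitness; rank weights when the spread is degenerate."""
    finite = np.where(np.isfinite(fits), fits, np.nan)
    lo = np.nanmin(finite)
    weights = np.where(np.isfinite(fits), fits - lo, 0.0)
    if weights.sum() <= 0:  # all equal or all invalid -> rank fallback
        order = np.argsort(np.argsort(np.nan_to_num(fits, nan=-np.inf)))
        weights = order + 1.0
        weights[~np.isfinite(fits)] = 0.0
    p = weights / weights.sum()
    idx = rng.choice(len(pop), size=len(pop), p=p)
    return idx


def evolve(X: DescriptorMatrix, y: ActivityVector, config: GAConfig) -> GAResult:
    """Run the GA and refit the best chromosome as a PLS model with CV-chosen LVs."""
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        config = replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    A = X.values
    yv = y.values
    names = X.names
    n, p = A.shape
    pop = initialize(config, p, rng)
    elite = None
    elite_fit = -np.inf
    history: list[dict] = []
    for gen in range(config.max_generations):
        folds = _subset_folds(n, config.n_subsets, rng)
        fits = np.empty(config.population)
        cache: dict[bytes, float] = {}
        for k in range(config.population):
            key = pop[k].tobytes()
            if key not in cache:
                cache[key] = fitness(pop[k], A, yv, folds, config.max_lv)[0]
            fits[k] = cache[key]
        # elitism: re-evaluate the stored elite under this generation's folds so
        # fitnesses are comparable, and never let the lineage regress
        if elite is not None:
            elite_now = fitness(elite, A, yv, folds, config.max_lv)[0]
            if elite_now > fits.max():
                worst = int(np.argmin(fits))
                pop[worst] = elite
                fits[worst] = elite_now
        g_best = int(np.argmax(fits))
        if elite is None or fits[g_best] >= elite_fit:
            elite = pop[g_best].copy()
        elite_fit = max(elite_fit, float(fits[g_best]))
        history.append(
            {
                "generation": gen,
                "best_fitness": float(fits[g_best]),
                "elite_fitness": float(elite_fit),
                "mean_fitness": float(np.mean(fits[np.isfinite(fits)])),
                "bits_on": int(pop[g_best].sum()),
            }
        )
        share = np.mean(np.isclose(fits, fits[g_best], rtol=0, atol=1e-12))
        if share >= config.convergence_fraction:
            break
        # next generation
        parents = _select_parents(pop, fits, rng)
        nxt = np.empty_like(pop)
        for k in range(0, config.population, 2):
            c1, c2 = _crossover(
                pop[parents[k]], pop[parents[k + 1]], config.crossover, rng
            )
            nxt[k], nxt[k + 1] = c1, c2
        if config.mutation_rate > 0:
            flips = rng.random(nxt.shape) < config.mutation_rate
            nxt ^= flips
        for k in range(config.population):  # keep chromosomes valid
            if not nxt[k].any():
                nxt[k, rng.integers(p)] = True
        nxt[0] = pop[g_best]  # elitism of the single best
        pop = nxt
    sub = X.subset([nm for nm, bit in zip(names, elite) if bit])
    folds = _subset_folds(n, config.n_subsets, np.random.default_rng(seed + 1))
    _, best_lv = fitness(elite, A, yv, folds, config.max_lv)
    rank = int(np.linalg.matrix_rank(sub.values - sub.values.mean(axis=0)))
    model = fit_pls(sub, y, min(best_lv, rank))
    return GAResult(
        best_chromosome=elite,
        best_names=sub.names,
        best_fitness=float(elite_fit),
        history=history,
        model=model,
    )
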