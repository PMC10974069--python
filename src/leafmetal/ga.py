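"""Genetic-algorithm wavelength selection scored by PLSR cross-validation.

Chromosomes are variable-cardinality boolean masks over channels; fitness is
the cross-validated RMSE of a PLSR model restricted to the masked channels
(at its own optimal component count), so lower is fitter.  The search runs a
fixed number of generations with tournament selection, uniform crossover,
per-gene bit-flip mutation and elitism, repeated ``n_repeats`` times with
derived sub-seeds; the best-of-repeats mask is returned together with
per-channel selection frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .plsr import cross_validate, default_max_ncomp

__all__ = ["GAConfig", "BandMask", "GARunRecord", "SelectionResult",
           "fitness", "evolve", "select_bands", "GAError"]

logger = logging.getLogger(__name__)


class GAError(ValueError):
    pass


@dataclass
class GAConfig:
    population_size: int = 40
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    n_generations: int = 100
    n_repeats: int = 10
    init_inclusion_prob: float = 0.10
    min_bands: int = 2
    elitism: int = 1
    seed: int = 0
    max_ncomp: int | None = None  # None -> min(10, n-2, mask size)

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "init_inclusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GAError(f"{name}={v} outside [0, 1]")
        if self.population_size < 2:
            raise GAError("population_size must be >= 2")
        if self.min_bands < 1:
            raise GAError("min_bands must be >= 1")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise GAError("elitism outside [0, population_size]")


@dataclass
class BandMask:
    included: np.ndarray  # bool over channels
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, bool)

    @property
    def n_bands(self) -> int:
        return int(self.included.sum())

    def wavelengths(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid)[self.included]


@dataclass
class GARunRecord:
    best_mask_per_generation: list[BandMask]
    final_best: BandMask
    repeat_index: int


@dataclass
class SelectionResult:
    best: BandMask
    records: list[GARunRecord]
    selection_frequency: np.ndarray  # per-channel fraction of repeats selecting it
    band_counts: list[int] = field(default_factory=list)


def fitness(mask: BandMask | np.ndarray, X: np.ndarray, y: np.ndarray,
            cv_scheme="loo", min_bands: int = 2,
            max_ncomp: int | None = None) -> float:
    """Cross-validated RMSE of PLSR on the masked channels (lower = fitter).

    Masks with fewer than ``min_bands`` channels score infinitely bad.
    The component count is re-optimized inside each evaluation.
    """
    included = mask.included if isinstance(mask, BandMask) else np.asarray(mask, bool)
    k = int(included.sum())
    if k < min_bands:
        logger.debug("mask with %d < %d bands: infinite fitness", k, min_bands)
        return float("inf")
    n = len(y)
    cap = default_max_ncomp(n, k)
    if max_ncomp is not None:
        cap = min(cap, max_ncomp)
    return cross_validate(X[:, included], y, max_ncomp=cap, scheme=cv_scheme).rmse_cv


def _evaluate_population(pop: np.ndarray, X, y, cv_scheme, config: GAConfig,
                         cache: dict) -> np.ndarray:
    fits = np.empty(len(pop))
    for i, mask in enumerate(pop):
        key = mask.tobytes()
        if key not in cache:
            cache[key] = fitness(mask, X, y, cv_scheme,
                                 min_bands=config.min_bands,
                                 max_ncomp=config.max_ncomp)
        fits[i] = cache[key]
    return fits


def _init_population(rng: np.random.Generator, config: GAConfig,
                     n_channels: int) -> np.ndarray:
    pop = rng.random((config.population_size, n_channels)) < config.init_inclusion_prob
    for i in range(config.population_size):
        while pop[i].sum() < config.min_bands:  # resample violators
            pop[i] = rng.random(n_channels) < max(config.init_inclusion_prob, 1e-3)
    return pop


def evolve(X: np.ndarray, y: np.ndarray, config: GAConfig,
           cv_scheme="loo", repeat_index: int = 0,
           rng: np.random.Generator | None = None,
           cache: dict | None = None) -> GARunRecord:
    """One GA run: fixed ``n_generations`` generations, best-per-generation trace."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n_channels = X.shape[1]
    if n_channels < config.min_bands:
        raise GAError("fewer channels than min_bands")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if cache is None:
        cache = {}

    pop = _init_population(rng, config, n_channels)
    fits = _evaluate_population(pop, X, y, cv_scheme, config, cache)
    trace: list[BandMask] = []

    for _gen in range(config.n_generations):
        order = np.argsort(fits, kind="stable")
        elites = pop[order[: config.elitism]].copy()
        best = order[0]
        trace.append(BandMask(pop[best].copy(), float(fits[best])))

        # tournament selection, size 2
        a = rng.integers(0, config.population_size, size=config.population_size)
        b = rng.integers(0, config.population_size, size=config.population_size)
        winners = np.where(fits[a] <= fits[b], a, b)
        children = pop[winners].copy()

        # uniform crossover on consecutive mated pairs
        for i in range(0, config.population_size - 1, 2):
            if rng.random() < config.crossover_prob:
                swap = rng.random(n_channels) < 0.5
                tmp = children[i, swap].copy()
                children[i, swap] = children[i + 1, swap]
                children[i + 1, swap] = tmp

        # per-gene bit-flip mutation
        if config.mutation_prob > 0:
            flips = rng.random(children.shape) < config.mutation_prob
            children ^= flips

        if config.elitism > 0:
            children[: config.elitism] = elites
        pop = children
        fits = _evaluate_population(pop, X, y, cv_scheme, config, cache)

    best = int(np.argsort(fits, kind="stable")[0])
    final = BandMask(pop[best].copy(), float(fits[best]))
    if trace and final.fitness > trace[-1].fitness:
        final = trace[-1]  # elitism guarantees this never triggers
    trace.append(BandMask(final.included.copy(), final.fitness))
    logger.debug("repeat %d: final fitness %.6g with %d bands",
                 repeat_index, final.fitness, final.n_bands)
    return GARunRecord(best_mask_per_generation=trace, final_best=final,
                       repeat_index=repeat_index)


def select_bands(X: np.ndarray, y: np.ndarray, config: GAConfig,
                 cv_scheme="loo") -> SelectionResult:
    """Repeat the GA ``n_repeats`` times (sub-seeds seed+r) and keep the
    lowest-fitness final mask; also report per-channel selection frequency
    and per-repeat band counts across the repeats."""
    X = np.atleast_2d(np.asarray(X, float))
    cache: dict = {}
    records = []
    for r in range(config.n_repeats):
        cfg_r = replace(config, seed=config.seed + r)
        rng = np.random.default_rng(cfg_r.seed)
        records.append(evolve(X, y, cfg_r, cv_scheme=cv_scheme,
                              repeat_index=r, rng=rng, cache=cache))
    finals = [rec.final_best for rec in records]
    fits = np.array([m.fitness for m in finals])
    best = finals[int(np.argmin(fits))]
    freq = np.mean([m.included for m in finals], axis=0)
    counts = [m.n_bands for m in finals]
    logger.info("GA selection: best fitness %.6g, %d bands; per-repeat counts %s",
                best.fitness, best.n_bands, counts)
    return SelectionResult(best=BandMask(best.included.copy(), best.fitness),
                           records=records, selection_frequency=freq,
                           band_counts=counts)
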