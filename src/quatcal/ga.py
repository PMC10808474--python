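"""Genetic-algorithm wavelength selection over contiguous windows.

Chromosomes are binary vectors over fixed-width windows of adjacent
wavelengths (default width 2).  Fitness is the cross-validated RMSECV of a
mean-centered PLS-1 model restricted to the selected wavelengths, averaged
over a small number of random k-fold partitions that are redrawn each
generation and shared by the whole population.  Selection is rank based
(top half breed), recombination is single-point crossover, mutation flips
genes independently, and the best chromosome always survives unchanged.

The all-selected chromosome is injected into the initial population, so
with elitism the final selection can never be less fit (by RMSECV) than
the full-spectrum model under the same partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import apply_preproc, fit_preproc, inverse_y
from .pls import nipals_pls1

__all__ = ["GAConfig", "Chromosome", "GAResult", "make_windows",
           "init_population", "fitness", "evolve", "run_ga",
           "GA_POPULATION", "GA_CONVERGENCE", "GA_MAX_LV", "default_ga_config"]

#: Per-analyte population sizes.
GA_POPULATION = {"CAF": 100, "COD": 200, "PAR": 100, "PAP": 20}
#: Per-analyte convergence thresholds (% of population identical to best).
GA_CONVERGENCE = {"CAF": 100.0, "COD": 50.0, "PAR": 100.0, "PAP": 100.0}
#: Per-analyte latent-variable caps for the fitness model.
GA_MAX_LV = {"CAF": 5, "COD": 4, "PAR": 3, "PAP": 6}


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    max_generations: int = 50
    mutation_rate: float = 0.005
    window_width: int = 2
    init_fraction: float = 0.5
    convergence_percent: float = 100.0
    max_lv: int = 5
    cv_subsets: int = 4
    cv_iterations: int = 2
    crossover: str = "single"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("invalid-config: mutation_rate must lie in [0, 1]")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("invalid-config: population_size must be even and >= 2")
        if self.cv_subsets < 2:
            raise ValueError("invalid-config: cv_subsets must be >= 2")


def default_ga_config(analyte: str, seed: int = 0, **overrides) -> GAConfig:
    """Per-analyte defaults: population, convergence threshold and LV cap."""
    kw = dict(
        population_size=GA_POPULATION[analyte],
        convergence_percent=GA_CONVERGENCE[analyte],
        max_lv=GA_MAX_LV[analyte],
        seed=seed,
    )
    kw.update(overrides)
    return GAConfig(**kw)


@dataclass(frozen=True)
class Chromosome:
    genes: np.ndarray          # boolean over windows
    fitness: float | None = None


@dataclass(frozen=True)
class GAResult:
    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray
    best_genes: np.ndarray
    best_fitness_trace: np.ndarray
    generations_run: int
    converged: bool
    config: GAConfig


def make_windows(grid_size: int, width: int) -> list[tuple[int, int]]:
    """Consecutive non-overlapping index ranges [start, stop).

    A final short window holds any remainder when width does not divide
    the grid size.
    """
    if width < 1:
        raise ValueError("invalid-width: width must be >= 1")
    if width > grid_size:
        raise ValueError("invalid-width: width exceeds grid size")
    return [(i, min(i + width, grid_size)) for i in range(0, grid_size, width)]


def _expand(genes: np.ndarray, windows) -> np.ndarray:
    """Window genes -> sorted wavelength column indices."""
    idx = [np.arange(a, b) for g, (a, b) in zip(genes, windows) if g]
    return np.concatenate(idx) if idx else np.empty(0, dtype=int)


def init_population(n_windows: int, config: GAConfig) -> list[Chromosome]:
    """Seeded Bernoulli(init_fraction) genes; empty chromosomes are redrawn.

    Member 0 is always the all-selected chromosome (full-spectrum
    baseline); with elitism this guarantees the GA never returns a
    selection whose fitness exceeds the full spectrum's.
    """
    rng = np.random.default_rng([config.seed, 0])
    pop = [Chromosome(np.ones(n_windows, dtype=bool))]
    while len(pop) < config.population_size:
        genes = rng.random(n_windows) < config.init_fraction
        if genes.any():
            pop.append(Chromosome(genes))
    return pop


def _cv_partitions(n: int, config: GAConfig, generation: int):
    """The generation's shared random k-fold partitions."""
    rng = np.random.default_rng([config.seed, 1, generation])
    parts = []
    for _ in range(config.cv_iterations):
        perm = rng.permutation(n)
        parts.append([np.sort(perm[i::config.cv_subsets]) for i in range(config.cv_subsets)])
    return parts


def _rmsecv_selected(X, y, cols, max_lv, partitions) -> float:
    """Pooled RMSECV of a mean-centered PLS-1 fit on selected columns."""
    n = X.shape[0]
    Xs = X[:, cols]
    per_iter = []
    for folds in partitions:
        sq = 0.0
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            lv = min(max_lv, len(train) - 1, len(cols))
            pre = fit_preproc(Xs[train], y[train], "mean_center")
            Xt, yt = apply_preproc(pre, Xs[train], y[train])
            _, _, _, B, _ = nipals_pls1(Xt, yt, lv)
            pred = inverse_y(pre, apply_preproc(pre, Xs[fold]) @ B[:, lv - 1])
            sq += float(np.sum((pred - y[fold]) ** 2))
        per_iter.append(np.sqrt(sq / n))
    return float(np.mean(per_iter))


def fitness(chromosome: Chromosome, X: np.ndarray, y: np.ndarray,
            config: GAConfig, generation: int = 0, windows=None,
            partitions=None) -> float:
    """RMSECV (µg/mL) of the chromosome's wavelength selection.

    Deterministic given (data, chromosome, config.seed, generation): the
    random partitions are drawn from the generation's seeded stream.
    """
    if windows is None:
        windows = make_windows(X.shape[1], config.window_width)
    if not chromosome.genes.any():
        raise ValueError("invalid-chromosome: no window selected")
    if partitions is None:
        partitions = _cv_partitions(X.shape[0], config, generation)
    cols = _expand(chromosome.genes, windows)
    return _rmsecv_selected(np.asarray(X, float), np.asarray(y, float).ravel(),
                            cols, config.max_lv, partitions)


def _repair(genes: np.ndarray, rng) -> np.ndarray:
    if not genes.any():
        genes = genes.copy()
        genes[rng.integers(len(genes))] = True
    return genes


def evolve(population: list[Chromosome], config: GAConfig, rng) -> list[Chromosome]:
    """One generation: rank selection, single-point crossover, mutation.

    ``population`` must already be evaluated (fitness set).  The fittest
    chromosome survives unchanged (elitism) and keeps its stored fitness.
    """
    ranked = sorted(population, key=lambda c: c.fitness)
    n = len(ranked)
    n_genes = len(ranked[0].genes)
    parents = ranked[: max(2, n // 2)]
    out = [ranked[0]]                       # elite, fitness retained
    while len(out) < n:
        i, j = rng.integers(len(parents)), rng.integers(len(parents))
        g1, g2 = parents[i].genes, parents[j].genes
        if config.crossover == "single" and n_genes > 1:
            cut = int(rng.integers(1, n_genes))
            c1 = np.concatenate([g1[:cut], g2[cut:]])
            c2 = np.concatenate([g2[:cut], g1[cut:]])
        else:
            c1, c2 = g1.copy(), g2.copy()
        for child in (c1, c2):
            if len(out) >= n:
                break
            if config.mutation_rate > 0:
                flip = rng.random(n_genes) < config.mutation_rate
                child = child ^ flip
            out.append(Chromosome(_repair(child, rng)))
    return out


def run_ga(X: np.ndarray, y: np.ndarray, config: GAConfig,
           wavelengths: np.ndarray | None = None) -> GAResult:
    """Evolve window selections until convergence or max_generations.

    Convergence: at least ``convergence_percent`` % of the population is
    gene-identical to the current best chromosome.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)
    windows = make_windows(X.shape[1], config.window_width)
    rng = np.random.default_rng([config.seed, 2])
    pop = init_population(len(windows), config)
    trace = []
    converged = False
    gens = 0
    for gen in range(config.max_generations):
        parts = _cv_partitions(X.shape[0], config, gen)
        pop = [
            c if c.fitness is not None
            else replace(c, fitness=_rmsecv_selected(
                X, y, _expand(c.genes, windows), config.max_lv, parts))
            for c in pop
        ]
        pop.sort(key=lambda c: c.fitness)
        best = pop[0]
        trace.append(best.fitness)
        gens = gen + 1
        share = np.mean([np.array_equal(c.genes, best.genes) for c in pop]) * 100.0
        if share >= config.convergence_percent:
            converged = True
            break
        if gen < config.max_generations - 1:
            pop = evolve(pop, config, rng)
    best = min(pop, key=lambda c: c.fitness)
    cols = _expand(best.genes, windows)
    return GAResult(
        selected_indices=cols,
        selected_wavelengths=np.asarray(wavelengths, float)[cols],
        best_genes=best.genes,
        best_fitness_trace=np.asarray(trace),
        generations_run=gens,
        converged=converged,
        config=config,
    )
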