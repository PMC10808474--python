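"""Genetic-algorithm wavelength selection: operators and full runs."""

import numpy as np
import pytest

from quatcal import ga
from quatcal import pls


@pytest.fixture(scope="module")
def band_data():
    """25 samples whose response depends on one 20-column band only."""
    rng = np.random.default_rng(21)
    lam = np.arange(210.0, 300.0)
    curve = 0.08 * np.exp(-((lam - 260.0) ** 2) / (2 * 8.0 ** 2))
    y = rng.uniform(1.0, 10.0, size=25)
    X = np.outer(y, curve) + rng.normal(0, 0.002, size=(25, 90))
    return X, y, lam


def small_cfg(**kw):
    base = dict(population_size=20, max_generations=8, max_lv=2, seed=0)
    base.update(kw)
    return ga.GAConfig(**base)


@pytest.mark.parametrize("grid,width,expected", [
    (90, 2, 45), (130, 2, 65), (90, 1, 90), (10, 3, 4),
])
def test_make_windows_counts(grid, width, expected):
    windows = ga.make_windows(grid, width)
    assert len(windows) == expected
    covered = np.concatenate([np.arange(a, b) for a, b in windows])
    np.testing.assert_array_equal(covered, np.arange(grid))
    with pytest.raises(ValueError, match="invalid-width"):
        ga.make_windows(grid, grid + 1)


def test_init_population_properties():
    cfg = small_cfg(population_size=100)
    pop = ga.init_population(45, cfg)
    assert len(pop) == 100
    # member 0 is the full-spectrum chromosome
    assert pop[0].genes.all()
    on = np.mean([c.genes.mean() for c in pop[1:]])
    assert 0.45 <= on <= 0.55
    assert all(c.genes.any() for c in pop)
    pop2 = ga.init_population(45, cfg)
    for a, b in zip(pop, pop2):
        np.testing.assert_array_equal(a.genes, b.genes)
    full = ga.init_population(45, small_cfg(init_fraction=1.0))
    assert all(c.genes.all() for c in full)


def test_fitness_all_ones_matches_direct_cv(band_data):
    """The all-windows chromosome scores exactly the pooled RMSECV of the
    same partitions, recomputed independently with the public PLS API."""
    X, y, _ = band_data
    cfg = small_cfg(cv_iterations=1)
    chrom = ga.Chromosome(np.ones(45, dtype=bool))
    got = ga.fitness(chrom, X, y, cfg, generation=0)
    parts = ga._cv_partitions(25, cfg, 0)[0]
    sq = 0.0
    for fold in parts:
        train = np.setdiff1d(np.arange(25), fold)
        model = pls.fit_pls1(X[train], y[train], cfg.max_lv, "mean_center")
        sq += np.sum((pls.predict(model, X[fold]) - y[fold]) ** 2)
    assert got == pytest.approx(np.sqrt(sq / 25), abs=1e-12)


def test_fitness_prefers_informative_band(band_data):
    X, y, lam = band_data
    cfg = small_cfg()
    genes_in = np.zeros(45, dtype=bool)
    genes_out = np.zeros(45, dtype=bool)
    for w, (a, b) in enumerate(ga.make_windows(90, 2)):
        centre = lam[a:b].mean()
        if 244 <= centre <= 276:
            genes_in[w] = True
        if centre <= 235:
            genes_out[w] = True
    f_in = ga.fitness(ga.Chromosome(genes_in), X, y, cfg)
    f_out = ga.fitness(ga.Chromosome(genes_out), X, y, cfg)
    assert f_in < f_out


def test_fitness_determinism_and_empty_rejection(band_data):
    X, y, _ = band_data
    cfg = small_cfg()
    chrom = ga.Chromosome(np.arange(45) % 3 == 0)
    assert ga.fitness(chrom, X, y, cfg, generation=2) == \
        ga.fitness(chrom, X, y, cfg, generation=2)
    assert ga.fitness(chrom, X, y, cfg, generation=2) != \
        ga.fitness(chrom, X, y, cfg, generation=3)
    with pytest.raises(ValueError, match="invalid-chromosome"):
        ga.fitness(ga.Chromosome(np.zeros(45, dtype=bool)), X, y, cfg)


def test_evolve_closure_without_mutation():
    """With mutation off and a population of identical parents, offspring
    are identical to the parents."""
    genes = np.arange(10) % 2 == 0
    pop = [ga.Chromosome(genes.copy(), fitness=1.0) for _ in range(6)]
    cfg = small_cfg(population_size=6, mutation_rate=0.0)
    out = ga.evolve(pop, cfg, np.random.default_rng(0))
    assert len(out) == 6
    for c in out:
        np.testing.assert_array_equal(c.genes, genes)


def test_evolve_elitism_and_full_mutation():
    rng = np.random.default_rng(1)
    pop = [ga.Chromosome(rng.random(12) < 0.5, fitness=float(i + 1))
           for i in range(8)]
    best = pop[0]
    cfg = small_cfg(population_size=8, mutation_rate=0.0)
    out = ga.evolve(pop, cfg, np.random.default_rng(2))
    np.testing.assert_array_equal(out[0].genes, best.genes)
    assert out[0].fitness == best.fitness
    # mutation_rate 1 flips every gene of the crossover output
    one_parent = [ga.Chromosome(np.ones(12, dtype=bool), fitness=1.0)] * 4
    flipped = ga.evolve(one_parent, small_cfg(population_size=4, mutation_rate=1.0),
                        np.random.default_rng(3))
    for c in flipped[1:]:
        # all-ones parents -> crossover gives all-ones -> full flip gives
        # all-zeros, repaired to a single on-gene
        assert c.genes.sum() == 1


def test_run_ga_trace_and_reproducibility(band_data):
    X, y, lam = band_data
    cfg = small_cfg(seed=5)
    res = ga.run_ga(X, y, cfg, wavelengths=lam)
    assert np.all(np.diff(res.best_fitness_trace) <= 1e-15)
    assert res.selected_indices.size > 0
    res2 = ga.run_ga(X, y, cfg, wavelengths=lam)
    np.testing.assert_array_equal(res.best_genes, res2.best_genes)
    np.testing.assert_array_equal(res.best_fitness_trace, res2.best_fitness_trace)
    # selection is a union of whole windows
    windows = ga.make_windows(90, cfg.window_width)
    sel = set(res.selected_indices.tolist())
    for a, b in windows:
        block = set(range(a, b))
        assert block <= sel or not (block & sel)


def test_run_ga_never_beats_full_spectrum_fitness(band_data):
    """Final best fitness <= the all-ones chromosome's first-generation
    fitness (the all-ones member is injected and elitism preserves rank)."""
    X, y, _ = band_data
    cfg = small_cfg(seed=9)
    res = ga.run_ga(X, y, cfg)
    full_first = ga.fitness(ga.Chromosome(np.ones(45, dtype=bool)), X, y,
                            cfg, generation=0)
    assert res.best_fitness_trace[-1] <= full_first + 1e-12


def test_run_ga_localizes_informative_band():
    """Across seeds, the GA keeps at least one window inside the only
    informative band (quick 5-seed check)."""
    from quatcal.experiments import informative_band_runs
    out = informative_band_runs(n_seeds=5, seed0=123)
    assert out["hits"] >= 4
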