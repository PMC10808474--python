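"""Reusable simulation experiments on the synthetic study.

These functions run the package end-to-end at reduced genetic-algorithm
problem sizes (population 20, 10 generations) so that multi-seed
experiments finish in minutes on one CPU; the full Table-style defaults
remain available through :class:`~quatcal.pipeline.StudyConfig`.
"""

from __future__ import annotations

import numpy as np

from . import ga as ga_mod
from . import spectra as sp
from .design import ANALYTES
from .pipeline import StudyConfig, StudyReport, run_study

__all__ = ["scaled_study_config", "noiseless_recovery", "run_seeded_studies",
           "ga_ann_recovery_stats", "ga_vs_pls_rmsep",
           "informative_band_runs"]

#: Reduced GA size used by the multi-seed experiments.
SCALED_GA = {"population_size": 20, "max_generations": 10}


def scaled_study_config(seed: int, noise_sd: float = sp.DEFAULT_NOISE_SD,
                        **overrides) -> StudyConfig:
    """Study configuration with the reduced GA size and a 3/10/30 hidden scan."""
    kw = dict(seed=seed, noise_sd=noise_sd, ga_overrides=dict(SCALED_GA),
              hidden_scan=(3, 10, 30))
    kw.update(overrides)
    return StudyConfig(**kw)


def noiseless_recovery(seed: int = 0) -> dict:
    """Noiseless end-to-end run; per-model per-analyte mean recovery (%)."""
    report = run_study(scaled_study_config(seed, noise_sd=0.0))
    out = {}
    for _, row in report.model_summary.iterrows():
        out[(row["model"], row["analyte"])] = float(row["mean_recovery_pct"])
    return out


def run_seeded_studies(seeds, noise_sd: float = sp.DEFAULT_NOISE_SD) -> list[StudyReport]:
    """One scaled study per seed."""
    return [run_study(scaled_study_config(s, noise_sd)) for s in seeds]


def ga_ann_recovery_stats(reports) -> list[dict]:
    """Per-seed GA-ANN recovery mean/SD per analyte, plus a pass flag.

    A seed passes when every analyte's GA-ANN mean recovery lies within
    100 +/- 2 % and its SD is at most 3 %.
    """
    out = []
    for rep in reports:
        ms = rep.model_summary
        row = {}
        ok = True
        for a in ANALYTES:
            r = ms[(ms.model == "GA-ANN") & (ms.analyte == a)].iloc[0]
            row[a] = (float(r.mean_recovery_pct), float(r.sd_recovery_pct))
            ok &= abs(r.mean_recovery_pct - 100.0) <= 2.0 and r.sd_recovery_pct <= 3.0
        row["pass"] = bool(ok)
        out.append(row)
    return out


def ga_vs_pls_rmsep(reports) -> dict:
    """Median over seeds of validation RMSEP for GA-PLS vs full PLS-1."""
    med = {}
    for a in ANALYTES:
        pls, gap = [], []
        for r in reports:
            ms = r.model_summary
            pls.append(float(ms[(ms.model == "PLS-1") & (ms.analyte == a)]
                             .rmsep_ug_ml.iloc[0]))
            gap.append(float(ms[(ms.model == "GA-PLS") & (ms.analyte == a)]
                             .rmsep_ug_ml.iloc[0]))
        med[a] = (float(np.median(pls)), float(np.median(gap)))
    return med


def informative_band_runs(n_seeds: int = 20, seed0: int = 0,
                          noise_sd: float = sp.DEFAULT_NOISE_SD) -> dict:
    """GA localization experiment on a single-band response.

    The spectra carry signal for y only inside one Gaussian band
    (centre 260 nm, sigma 8 nm on the 90-point window); everything else is
    noise.  For each seed a small GA runs and we record whether at least
    one selected window falls inside the +/- 3 sigma band region.
    """
    grid = sp.make_grid(210.0, 300.0, 1.0)
    lam = grid.points
    center, width = 260.0, 8.0
    curve = 0.08 * np.exp(-((lam - center) ** 2) / (2.0 * width ** 2))
    band_lo, band_hi = center - 3 * width, center + 3 * width
    n = 25
    hits = 0
    per_seed = []
    for k in range(n_seeds):
        rng = np.random.default_rng([seed0, 17, k])
        y = rng.uniform(1.0, 10.0, size=n)
        X = np.outer(y, curve) + rng.normal(0.0, noise_sd, size=(n, len(lam)))
        cfg = ga_mod.GAConfig(population_size=20, max_generations=10,
                              max_lv=2, seed=int(rng.integers(2**31)))
        res = ga_mod.run_ga(X, y, cfg, wavelengths=lam)
        in_band = np.any((res.selected_wavelengths >= band_lo)
                         & (res.selected_wavelengths <= band_hi))
        hits += bool(in_band)
        per_seed.append(bool(in_band))
    return {"hits": hits, "n_seeds": n_seeds, "per_seed": per_seed,
            "band_nm": (band_lo, band_hi)}
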