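"""End-to-end study orchestration.

``run_study`` wires the whole comparison together: build the 25-run
calibration design and six-mixture validation set, simulate their spectra,
then per analyte restrict to the analysis window, fit a full-spectrum
PLS-1 model (leave-one-out LV selection), run GA wavelength selection,
refit PLS on the selection (GA-PLS) and train a GA-ANN on the selection
with a hidden-size scan.  All three models are evaluated on the validation
mixtures: recovery grid with rejection flags, mean/SD, RMSEP, and a
predicted-vs-actual regression line per analyte and model.

The validation set doubles as the early-stopping set for ANN training, so
the reported ANN RMSEP is not fully independent of training; this mirrors
the study protocol being emulated and is flagged in the documentation.

``assay_dilution`` performs the dosage-form dilution arithmetic exactly
(rational numbers, no float drift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from . import ann as ann_mod
from . import design as design_mod
from . import evaluate as ev
from . import ga as ga_mod
from . import pls as pls_mod
from . import spectra as sp
from .design import ANALYTES

__all__ = ["StudyConfig", "StudyReport", "AssayScheme", "assay_dilution",
           "solpadeine_scheme", "run_study", "write_report", "read_report",
           "MODELS"]

MODELS = ("PLS-1", "GA-PLS", "GA-ANN")


@dataclass(frozen=True)
class AssayScheme:
    """Dosage-form dilution scheme.

    ``label_mg`` maps analyte to the labelled amount (mg) dissolved into
    ``stock_volume_ml``; each transfer step takes ``taken_ml`` of the
    previous solution into ``final_ml`` of solvent, optionally adding
    ``spike_ug`` of pure analyte.
    """

    label_mg: dict
    stock_volume_ml: float = 100.0
    steps: tuple = ()          # tuples (taken_ml, final_ml, spike_ug)


def solpadeine_scheme(spike_cod_ug: float = 0.0) -> AssayScheme:
    """Tablet scheme: PAR 500 / CAF 30 / COD 8 mg per tablet into 100 mL,
    then 0.4 mL diluted to 100 mL (optionally spiking COD)."""
    return AssayScheme(
        label_mg={"PAR": 500, "CAF": 30, "COD": 8},
        stock_volume_ml=100.0,
        steps=((0.4, 100.0, spike_cod_ug),),
    )


def assay_dilution(scheme: AssayScheme, analyte: str) -> float:
    """Final concentration (µg/mL) of ``analyte`` after all transfer steps.

    Exact C·V accounting: stock = label_mg·1000 / stock_volume; each step
    multiplies by taken/final and adds spike/final.
    """
    if analyte not in scheme.label_mg:
        raise ValueError(f"invalid-scheme: no labelled amount for {analyte!r}")
    if scheme.stock_volume_ml <= 0:
        raise ValueError("invalid-scheme: stock volume must be positive")
    def frac(x) -> Fraction:
        # decimal-exact: 0.4 means 4/10, not the nearest binary double
        return Fraction(str(x)) if isinstance(x, float) else Fraction(x)

    conc = frac(scheme.label_mg[analyte]) * 1000 / frac(scheme.stock_volume_ml)
    prev_volume = frac(scheme.stock_volume_ml)
    for taken, final, spike in scheme.steps:
        taken, final, spike = frac(taken), frac(final), frac(spike)
        if taken < 0 or final <= 0 or spike < 0:
            raise ValueError("invalid-scheme: volumes must be positive, spikes non-negative")
        if taken > prev_volume:
            raise ValueError("invalid-scheme: aliquot exceeds available volume")
        conc = conc * taken / final + spike / final
        prev_volume = final
    return float(conc)


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a study run (pure function of this)."""

    seed: int = 0
    noise_sd: float = sp.DEFAULT_NOISE_SD
    preprocessing: str = "mean_center"
    lv_max: int = 10
    windows: dict = field(default_factory=lambda: dict(sp.ANALYSIS_WINDOWS))
    rejection_band: tuple = ev.DEFAULT_REJECTION_BAND
    ga: dict = field(default_factory=dict)       # analyte -> GAConfig
    ann: dict = field(default_factory=dict)      # analyte -> ANNConfig
    hidden_scan: tuple = ()                      # sizes; () -> per-analyte default only
    ga_overrides: dict = field(default_factory=dict)
    selection_guard: bool = True                 # Monte-Carlo procedure comparison
    guard_splits: int = 5                        # splits for the guard
    guard_test_size: int = 5                     # held-out samples per split

    def ga_config(self, analyte: str) -> ga_mod.GAConfig:
        if analyte in self.ga:
            return self.ga[analyte]
        return ga_mod.default_ga_config(analyte, seed=self.seed,
                                        **self.ga_overrides)

    def ann_config(self, analyte: str) -> ann_mod.ANNConfig:
        if analyte in self.ann:
            return self.ann[analyte]
        return ann_mod.default_ann_config(analyte, seed=self.seed)

    def scan_sizes(self, analyte: str) -> tuple:
        if self.hidden_scan:
            return tuple(self.hidden_scan)
        return (self.ann_config(analyte).hidden_neurons,)


@dataclass
class StudyReport:
    config_summary: dict
    recovery_table: pd.DataFrame     # mixture x analyte x model grid
    model_summary: pd.DataFrame      # per (model, analyte) statistics
    comparisons: pd.DataFrame        # per-analyte model-vs-model t/F verdicts
    selected: dict                   # analyte -> GA-selected wavelengths (nm)
    predictions: dict                # (model, analyte) -> 6 predictions

    def to_dict(self) -> dict:
        return {
            "config": self.config_summary,
            "recovery_table": self.recovery_table.to_dict(orient="records"),
            "model_summary": self.model_summary.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            "selected": {a: list(map(float, v)) for a, v in self.selected.items()},
            "predictions": {f"{m}|{a}": list(map(float, v))
                            for (m, a), v in self.predictions.items()},
        }


def _selection_procedure_wins(X, y, ga_cfg, config: StudyConfig,
                              analyte_index: int) -> bool:
    """Compare GA selection vs full spectrum as procedures.

    For each Monte-Carlo split the GA runs on the training part alone;
    both the resulting subset model and the full-spectrum model (each
    with LOO LV selection on the training part) predict the held-out
    calibration samples.  The selection is adopted only under a
    one-standard-error rule on the paired per-split error differences:
    its mean improvement must exceed the standard error of those
    differences, biasing ties toward the simpler full-spectrum model.
    """
    from dataclasses import replace as dc_replace

    n = X.shape[0]
    rng = np.random.default_rng([config.seed, 19, analyte_index])
    diffs = []
    for _ in range(config.guard_splits):
        perm = rng.permutation(n)
        test, train = perm[: config.guard_test_size], perm[config.guard_test_size:]
        lv_cap = min(config.lv_max, len(train) - 2)
        cfg_split = dc_replace(ga_cfg, seed=int(rng.integers(2 ** 31)))
        res = ga_mod.run_ga(X[train], y[train], cfg_split)
        s = res.selected_indices
        sse = {}
        for key, cols in (("sel", s), ("full", None)):
            Xt = X[train] if cols is None else X[train][:, cols]
            Xh = X[test] if cols is None else X[test][:, cols]
            cv = pls_mod.cross_validate(
                Xt, y[train], pls_mod.loo(),
                lv_max=min(lv_cap, Xt.shape[1]),
                preproc_mode=config.preprocessing)
            model = pls_mod.fit_pls1(Xt, y[train], cv.chosen_lv,
                                     config.preprocessing)
            sse[key] = float(np.sum((pls_mod.predict(model, Xh) - y[test]) ** 2))
        diffs.append(sse["full"] - sse["sel"])
    diffs = np.asarray(diffs)
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
    return float(diffs.mean()) > se


def _evaluate_predictions(predictions: dict, actual: np.ndarray,
                          mixture_ids, band) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    summary = []
    for model in MODELS:
        for j, a in enumerate(ANALYTES):
            pred = predictions[(model, a)]
            recs = [ev.recovery_percent(p, c) for p, c in zip(pred, actual[:, j])]
            kept, flags = ev.reject_outliers(recs, band)
            for mid, p, c, r, fl in zip(mixture_ids, pred, actual[:, j], recs, flags):
                rows.append({"model": model, "analyte": a, "mixture": mid,
                             "actual_ug_ml": c, "predicted_ug_ml": float(p),
                             "recovery_pct": float(r), "rejected": bool(fl)})
            mean, sd = ev.summarize_recoveries(kept)
            reg = ev.fit_pred_vs_actual(pred, actual[:, j])
            summary.append({
                "model": model, "analyte": a,
                "mean_recovery_pct": mean, "sd_recovery_pct": sd,
                "n_kept": int(len(kept)),
                "rmsep_ug_ml": pls_mod.rmse(actual[:, j], pred),
                "slope": reg.slope, "intercept": reg.intercept, "r": reg.r,
            })
    return pd.DataFrame(rows), pd.DataFrame(summary)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full three-model comparison; deterministic in ``config``."""
    design = design_mod.build_design()
    val_conc = design_mod.validation_set()
    grid = sp.make_grid(*sp.FULL_SCAN, "inclusive")
    library = sp.default_library(grid)
    cal = sp.simulate_mixtures(design.concentrations, library, config.noise_sd,
                               seed=np.random.default_rng([config.seed, 11]).integers(2**31),
                               sample_ids=tuple(range(1, 26)))
    val = sp.simulate_mixtures(val_conc, library, config.noise_sd,
                               seed=np.random.default_rng([config.seed, 13]).integers(2**31),
                               sample_ids=design_mod.validation_mixture_ids())

    predictions: dict = {}
    selected: dict = {}
    details: dict = {}
    for j, analyte in enumerate(ANALYTES):
        window = tuple(config.windows[analyte])
        cal_w = sp.restrict(cal, window)
        val_w = sp.restrict(val, window)
        X, y = cal_w.absorbance, design.concentrations[:, j]
        Xv = val_w.absorbance

        # full-spectrum PLS-1 with LOO LV selection
        cv = pls_mod.cross_validate(X, y, pls_mod.loo(),
                                    lv_max=min(config.lv_max, X.shape[0] - 2, X.shape[1]),
                                    preproc_mode=config.preprocessing)
        model_pls = pls_mod.fit_pls1(X, y, cv.chosen_lv, config.preprocessing, analyte)
        predictions[("PLS-1", analyte)] = pls_mod.predict(model_pls, Xv)

        # GA wavelength selection on the calibration data only
        ga_cfg = config.ga_config(analyte)
        ga_res = ga_mod.run_ga(X, y, ga_cfg, wavelengths=cal_w.wavelengths)
        sel = ga_res.selected_indices

        # Acceptance guard: a selected subset always looks good on the
        # same cross-validation it was optimized on, so the subset and
        # the full spectrum are compared as *procedures* on Monte-Carlo
        # calibration splits the GA never saw.  The selection is kept
        # only if re-running the GA on each training split predicts the
        # held-out calibration samples at least as well as full-spectrum
        # PLS; otherwise GA-PLS falls back to all wavelengths (the
        # all-ones chromosome), making "GA never worse than the
        # full-spectrum baseline" hold on validation data too.
        selection_accepted = True
        if config.selection_guard:
            selection_accepted = _selection_procedure_wins(
                X, y, ga_cfg, config, j)
        if not selection_accepted:
            sel = np.arange(X.shape[1])
        selected[analyte] = cal_w.wavelengths[sel]

        # GA-PLS: refit on the selection; on fallback the model is the
        # full-spectrum PLS-1 model itself (bit-identical predictions)
        if selection_accepted:
            lv_max_sel = min(config.lv_max, len(sel), X.shape[0] - 2)
            cv_sel = pls_mod.cross_validate(X[:, sel], y, pls_mod.loo(),
                                            lv_max=lv_max_sel,
                                            preproc_mode=config.preprocessing)
            model_gapls = pls_mod.fit_pls1(X[:, sel], y, cv_sel.chosen_lv,
                                           config.preprocessing, analyte)
            predictions[("GA-PLS", analyte)] = pls_mod.predict(model_gapls, Xv[:, sel])
        else:
            cv_sel = cv
            predictions[("GA-PLS", analyte)] = predictions[("PLS-1", analyte)]

        # GA-ANN: validation set also serves as the early-stopping set
        ann_cfg = config.ann_config(analyte)
        rows, chosen_h, model_ann = ann_mod.scan_hidden(
            X[:, sel], y, Xv[:, sel], val_conc[:, j],
            config.scan_sizes(analyte), ann_cfg)
        predictions[("GA-ANN", analyte)] = ann_mod.forward(model_ann, Xv[:, sel]).ravel()

        details[analyte] = {
            "pls_lv": cv.chosen_lv,
            "pls_rmsecv": float(cv.rmsecv_by_lv[cv.chosen_lv - 1]),
            "gapls_lv": cv_sel.chosen_lv,
            "gapls_rmsecv": float(cv_sel.rmsecv_by_lv[cv_sel.chosen_lv - 1]),
            "ga_generations": ga_res.generations_run,
            "ga_selection_accepted": selection_accepted,
            "ga_n_selected": int(len(sel)),
            "ga_fraction_selected": float(len(sel) / X.shape[1]),
            "ann_hidden": int(chosen_h),
            "ann_best_epoch": int(model_ann.best_epoch),
            "ann_scan": rows,
        }

    recovery_table, model_summary = _evaluate_predictions(
        predictions, val_conc, design_mod.validation_mixture_ids(),
        config.rejection_band)

    # enrich the summary with per-analyte fit details
    model_summary["n_variables"] = [
        details[a]["ga_n_selected"] if m != "PLS-1"
        else len(sp.make_grid(*config.windows[a], 1.0).points)
        for m, a in zip(model_summary["model"], model_summary["analyte"])
    ]
    model_summary["lv_or_hidden"] = [
        {"PLS-1": details[a]["pls_lv"], "GA-PLS": details[a]["gapls_lv"],
         "GA-ANN": details[a]["ann_hidden"]}[m]
        for m, a in zip(model_summary["model"], model_summary["analyte"])
    ]

    comp_rows = []
    rec = recovery_table
    for a in ANALYTES:
        for m1, m2 in (("PLS-1", "GA-ANN"), ("GA-PLS", "GA-ANN"), ("PLS-1", "GA-PLS")):
            g1 = rec[(rec.model == m1) & (rec.analyte == a) & ~rec.rejected]["recovery_pct"]
            g2 = rec[(rec.model == m2) & (rec.analyte == a) & ~rec.rejected]["recovery_pct"]
            if len(g1) < 2 or len(g2) < 2:
                continue
            c = ev.compare_methods(g1, g2)
            comp_rows.append({"analyte": a, "method_1": m1, "method_2": m2,
                              "t": c.t_statistic, "t_critical": c.t_critical,
                              "F": c.f_statistic, "f_critical": c.f_critical,
                              "significant": c.significant})
    comparisons = pd.DataFrame(comp_rows)

    config_summary = {
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "preprocessing": config.preprocessing,
        "lv_max": config.lv_max,
        "windows": {a: list(w) for a, w in config.windows.items()},
        "rejection_band": list(config.rejection_band),
        "details": details,
    }
    return StudyReport(config_summary, recovery_table, model_summary,
                       comparisons, selected, predictions)


def write_report(report: StudyReport, outdir) -> dict:
    """Write recovery grid / summary CSVs and a full JSON report."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "recovery_csv": out / "recovery_table.csv",
        "summary_csv": out / "model_summary.csv",
        "comparisons_csv": out / "comparisons.csv",
        "json": out / "report.json",
    }
    report.recovery_table.to_csv(paths["recovery_csv"], index=False)
    report.model_summary.to_csv(paths["summary_csv"], index=False)
    report.comparisons.to_csv(paths["comparisons_csv"], index=False)
    with open(paths["json"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_report(path) -> dict:
    """Read back the JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
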