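# quatcal

Chemometric resolution of a severely overlapping four-component UV mixture:
the analgesics **paracetamol** (PAR) and **codeine** (COD), the stimulant
**caffeine** (CAF), and paracetamol's toxic impurity **p-aminophenol**
(PAP). The four compounds absorb on top of each other across 210–340 nm, so
no single wavelength quantifies any of them; `quatcal` implements the full
multivariate-calibration workflow that resolves the mixture from whole
spectra, and a synthetic spectra generator so the workflow can be exercised,
tested and benchmarked without a spectrophotometer.

The package is aimed at analytical chemists and chemometricians who want a
tested, scriptable reference implementation of the classic
PLS-1 / GA–PLS / GA–ANN comparison on designed calibration mixtures.

## What it implements

- **Calibration design** (`quatcal.design`): a five-level, four-factor
  design in 25 runs. Run 1 sits at the centre levels (3.6, 8, 12, 4.5
  µg/mL for CAF, COD, PAR, PAP); runs 2–25 take their coded levels
  (−2 … +2) from a single 24-element generator sequence, cyclically shifted
  by one position per factor, so every code appears exactly five times per
  factor. A fixed six-mixture validation set accompanies it.
- **Synthetic spectra** (`quatcal.spectra`): Gaussian-band pure spectra with
  short-wavelength end absorption, mixed by the Beer–Lambert law
  `A(λ) = Σ_k c_k ε_k(λ)` at 1 cm path, plus additive homoscedastic
  Gaussian noise (default σ = 0.002 AU). Analysis windows 210–300 nm
  (CAF/COD/PAR, 90 variables) and 210–340 nm (PAP, 130 variables) at 1 nm.
- **PLS-1** (`quatcal.pls`): NIPALS with X/y deflation, one model per
  analyte; regression vector `b = W(PᵀW)⁻¹q`; leave-one-out
  cross-validation selects the latent-variable count minimizing RMSECV.
- **GA wavelength selection** (`quatcal.ga`): binary chromosomes over
  2-wavelength windows, fitness = RMSECV of a mean-centered PLS fit over
  random 4-fold partitions (2 repetitions per generation), rank selection,
  single-point crossover, mutation rate 0.005, elitism, and the
  full-spectrum chromosome injected at initiation.
- **GA–ANN** (`quatcal.ann`): one-hidden-layer feed-forward networks
  (linear, tansig or logsig hidden transfer; linear output), trained by
  Levenberg–Marquardt `Δw = −(JᵀJ + μI)⁻¹Jᵀe` with adaptive damping and
  validation-based early stopping.
- **Evaluation** (`quatcal.evaluate`): recovery % (100·predicted/actual)
  with a configurable rejection band (default 97.0–104.5 %),
  predicted-vs-actual regression, pooled-variance t test, variance-ratio F
  test and their critical values.
- **Pipeline** (`quatcal.pipeline`): the full three-model comparison as a
  pure function of a `StudyConfig`, plus exact rational dosage-form
  dilution arithmetic.

## Worked example

```python
import quatcal as qc

cfg = qc.StudyConfig(seed=1, noise_sd=0.002,
                     ga_overrides={"population_size": 20, "max_generations": 10},
                     hidden_scan=(3, 10, 30))
report = qc.run_study(cfg)
print(report.model_summary[["model", "analyte", "mean_recovery_pct",
                            "sd_recovery_pct", "rmsep_ug_ml"]].to_string(index=False))
```

prints (seed 1):

```
 model analyte  mean_recovery_pct  sd_recovery_pct  rmsep_ug_ml
 PLS-1     CAF         100.143640         0.168438     0.008508
 PLS-1     COD          99.950266         0.173212     0.006674
 PLS-1     PAR          99.981850         0.212045     0.009008
 PLS-1     PAP         100.167394         0.477743     0.010567
GA-PLS     CAF         100.143640         0.168438     0.008508
GA-PLS     COD          99.950266         0.173212     0.006674
GA-PLS     PAR          99.981850         0.212045     0.009008
GA-PLS     PAP         100.167394         0.477743     0.010567
GA-ANN     CAF         100.290451         0.317923     0.014251
GA-ANN     COD          99.713397         0.590508     0.020906
GA-ANN     PAR          99.942117         0.388093     0.017914
GA-ANN     PAP         100.381584         2.614204     0.054590
```

Each row summarizes one model's six validation-mixture predictions for one
analyte: the mean and SD of recovery (predicted/actual × 100, after the
rejection band) and the root-mean-square error of prediction in µg/mL. At
this noise level every model recovers all four analytes within a fraction
of a percent. GA–PLS equals PLS-1 here because the selection guard
(see `docs/methods.md`) found no wavelength subset that genuinely beats the
full spectrum under independent-and-identically-distributed noise and fell
back to all wavelengths.

The same study is available from the shell:

```bash
quatcal design --out design.csv
quatcal simulate --design design.csv --noise-sd 0.002 --seed 7 --out spectra.csv
quatcal run-all --seed 1 --out results/
```

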