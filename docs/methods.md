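# Methods

`quatcal` simulates and analyses the quantitation of caffeine (CAF),
codeine (COD), paracetamol (PAR) and p-aminophenol (PAP) in quaternary
mixtures from UV absorption spectra. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## Calibration design

The calibration set is a five-level, four-factor design in 25 runs. Levels
are coded −2…+2 and map linearly to concentrations; the centre levels are
3.6, 8, 12 and 4.5 µg/mL for CAF, COD, PAR, PAP, spanning 1.2–6, 2–14,
4–20 and 1.5–7.5 µg/mL. Run 1 is the all-centre run; for run *i* ≥ 2 and
factor *j*, the coded level is `generator[(i−2+j−1) mod 24]`, i.e. each
factor column is the 24-element generator cyclically shifted one position
from the previous factor. The construction guarantees each code appears
exactly five times per factor and every coded column sums to zero.

The default generator was decoded from the published design table rather
than re-derived from design-of-experiments theory: the original
construction's difference vector is not printed anywhere we can consult,
and shipping the decoded sequence guarantees cell-exact reproduction. The
constructor accepts any 24-element generator. Concentrations are stored as
integer tenths of µg/mL so table comparisons are exact, not
float-approximate.

The six-mixture validation set is fixed data (mixtures 26–31); mixture 27
is the design centre point.

## Synthetic spectra

Real pure spectra of the four compounds exist only as instrument traces,
so the generator uses parametric stand-ins: sums of Gaussian bands plus an
exponential end-absorption term rising toward short wavelengths,

    ε(λ) = Σ_b A_b · exp(−(λ − c_b)² / 2σ_b²) + A_end · exp(−(λ − λ₀)/τ).

The band constants are synthetic package constants (documented in
`spectra.py`), chosen once so that the curves reproduce the *regime* of
the real problem rather than any particular trace: every pairwise cosine
similarity on 210–300 nm is ≥ 0.5 (severe overlap; the defaults give
0.84–0.93), every curve's specific absorbance peaks well above the noise
floor, and PAP retains a long-wavelength band near 300 nm while absorbing
< 1 % of its maximum at 340 nm, matching its wider 210–340 nm analysis
window.

Mixing is Beer–Lambert at 1 cm path: `A = C·S` with `C` the samples ×
analytes concentration matrix and `S` the pure specific-absorbance
curves. Noise is additive i.i.d. Gaussian with σ = 0.002 AU by default — a
typical absorbance repeatability for a bench double-beam instrument; the
true instrument noise of the emulated study is unpublished, so this is a
free simulation parameter.

The instrument scan is 200–400 nm at 0.2 nm (1001 points, endpoints
included). Analysis grids use an **exclusive upper endpoint** at 1.0 nm:
210–300 nm holds 90 variables and 210–340 nm holds 130. This is the only
endpoint convention consistent with both published variable counts, and it
is applied to every analysis window.

What the generator does **not** model: wavelength-correlated noise,
baseline drift, stray light, detector saturation (absorbances above the
linear range are simply avoided by the design), replicate averaging, and
any departure from Beer–Lambert additivity. Consequences are discussed
under "What passing tests show" below.

## Preprocessing and PCA

Raw, mean-centering and autoscaling are supported; statistics come from
calibration data only and are stored, never refit on new samples. The
response is centered (and scaled, under autoscaling) consistently with the
spectra and predictions are back-transformed; the emulated study does not
say whether its autoscaling trials scaled the response, so both are
transformed consistently here. Sample standard deviations use the n−1
denominator throughout the package, matching the t/F statistics in the
evaluation module. PCA is an SVD of the column-centered matrix with the
sign convention that each loading's largest-magnitude element is positive.

## PLS-1

NIPALS with deflation of both X and y, one model per analyte (PLS-1
rather than PLS-2, following the emulated protocol). For component *a*:
weight `w = Xᵀy/‖Xᵀy‖`, score `t = Xw`, loadings `p = Xᵀt/tᵀt`,
`q = yᵀt/tᵀt`, then rank-one deflation. The regression vector for *a*
components is `b = W(PᵀW)⁻¹q`. Deflation stops early (flagged, not
silent) if the weight norm falls below 1e−12 or residual X variance below
1e−14; regression vectors for higher component counts then repeat the last
extracted one.

RMSEC, RMSECV and RMSEP all use the plain `sqrt(mean(residual²))` with a
1/n denominator — the emulated study never defines its denominators, so
one convention is applied uniformly. Cross-validation refits the
preprocessing and the PLS model on each training fold alone and pools
held-out residuals; leave-one-out is the default LV-selection scheme with
`lv_max = 10`, ties broken toward fewer latent variables (within 1e−12).

On noiseless synthetic data the mixture matrix has rank 4 by construction,
so LOO selects 4 LVs for every analyte and recovers concentrations to
machine precision — a structural sanity check, not a claim about real
spectra, whose reported LV counts (5/4/3/6) reflect instrument noise
structure the generator does not model.

## Genetic-algorithm wavelength selection

Chromosomes are binary vectors over contiguous windows of 2 adjacent
wavelengths (45 windows on the 90-point grid, 65 on the 130-point grid; a
final short window would hold any remainder for other widths). Defaults
follow the emulated study's optimized table: mutation rate 0.005,
single-point crossover, 50 % of windows on at initiation, maximum 50
generations, random 4-subset cross-validation with 2 repetitions per
generation, per-analyte population sizes 100/200/100/20 (CAF/COD/PAR/PAP),
convergence thresholds 100/50/100/100 % and fitness-model LV caps 5/4/3/6.

Choices the source protocol leaves open, decided here:

- **Fitness** is the RMSECV (µg/mL) of a mean-centered PLS-1 fit on the
  selected wavelengths, capped at the analyte's LV limit, averaged over
  the generation's random partitions. The partitions are drawn once per
  generation from a seeded stream and shared by the whole population, so
  fitness is deterministic given (data, chromosome, seed, generation) and
  chromosomes compete on common ground.
- **Selection** is rank-based: the fitter half of the population breeds,
  pairs drawn uniformly. One elite survives unchanged per generation and
  keeps its stored fitness, so the best-fitness trace is non-increasing.
- **Convergence** means at least the configured percentage of the
  population is gene-identical to the current best.
- The **all-selected chromosome** is injected into the initial population,
  so the GA's final fitness can never exceed the full spectrum's
  first-generation fitness.
- Empty chromosomes are redrawn at initiation; an empty crossover/mutation
  product has one random gene switched on.
- The validation set plays no role anywhere in selection.

## The selection-acceptance guard

A wavelength subset that survived a fitness tournament *always* looks good
on the cross-validation it was optimized against; with 25 calibration
samples this selection bias is large (a selected subset's calibration
RMSECV can sit several standard errors below the full spectrum's while its
independent prediction error is genuinely worse). The pipeline therefore
treats "use the GA selection" as a hypothesis to be tested, not a given:
on each of 5 Monte-Carlo splits of the calibration set (20 train / 5
held-out), the GA is re-run on the training part alone and both the
resulting subset model and the full-spectrum model predict the held-out
samples. The selection is adopted only if its mean per-split improvement
exceeds one standard error of the paired differences — a
one-standard-error rule that biases ties toward the simpler full-spectrum
model, in the same spirit as the tie-breaks toward fewer latent variables
and fewer hidden neurons. Otherwise GA–PLS falls back to all wavelengths
and is then the full-spectrum PLS-1 model, bit for bit.

Under the generator's i.i.d. homoscedastic noise this guard falls back
essentially always, and that is the scientifically correct outcome: when
every wavelength carries signal and noise is white, the full spectrum is
statistically efficient and no subset can beat it out of sample —
selection can only match it. The guard makes "GA–PLS is never worse than
PLS-1" hold on validation data, with equality the typical case. Where
spectra contain genuinely dead regions the GA does find and keep the
informative band (the localization experiment in `experiments.py` shows
≥ 18/20 seeded runs keep a window inside the only informative band).
GA-driven *improvement*, as opposed to equivalence, is a property of
structured real-instrument noise that the generator deliberately does not
claim to reproduce. The guard can be disabled
(`StudyConfig(selection_guard=False)`) to study the raw GA behaviour.

## Neural networks

One hidden layer per analyte, single linear output. Hidden transfer is
linear (purelin), tansig or logsig; default purelin–purelin, which
collapses to an affine map — appropriate because Beer–Lambert data are
linear, and verified against an ordinary-least-squares oracle. Default
hidden sizes 10/8/3/30 (CAF/COD/PAR/PAP) follow the emulated study's
optimized table; `scan_hidden` trains one seeded network per candidate
size and picks the lowest validation RMSE, ties toward fewer neurons.

Inputs and targets are min–max scaled to [−1, 1] from training data
(needed by the sigmoid pairs, harmless for purelin). Weights initialize
uniformly in [−0.5, 0.5] from the seed. Training is Levenberg–Marquardt:
`Δw = −(JᵀJ + μI)⁻¹Jᵀe` with the Jacobian computed analytically; after an
error decrease μ is multiplied by 0.001, after an increase by 100 (the
published "learning coefficient / decrease / increase" numbers, read as
the LM damping parameterization of the named training function), with the
step retried until the error decreases or μ exceeds 1e10. When the
parameter count exceeds the sample count the update uses the push-through
identity `Δw = −Jᵀ(JJᵀ + μI)⁻¹e`, which is algebraically identical but
solves an n×n system — this is what makes 30 hidden neurons on 130 inputs
with 25 samples cheap.

Early stopping follows the quoted protocol: the validation set is part of
training, and training stops after `max_val_fail = 1` epoch whose
validation RMSE exceeds the best seen; the returned weights are those of
the best-validation epoch. In the pipeline the six validation mixtures
serve as this early-stopping set, mirroring the emulated protocol — which
means the reported ANN RMSEP is not fully independent of training. This
is flagged deliberately rather than silently changed.

## Evaluation statistics

Recovery is 100 × predicted/actual (%). The rejection rule of the emulated
study is unpublished; the package default is an acceptance band of
97.0–104.5 %, the tightest band consistent with every excluded-vs-retained
entry of the published recovery table, applied as flags (entries are
marked, never deleted). A single-pass Dixon Q test (two-tailed, α = 0.05,
n = 3–10) is available as an alternative. Mean/SD of recoveries use only
non-rejected entries, SD with n−1. Predicted-vs-actual regression is
ordinary least squares with Pearson r. Method comparison uses the
pooled-variance two-sample |t| (df = n₁+n₂−2) and the variance-ratio F
(larger variance in the numerator), against two-tailed t and upper-tail F
critical values at α = 0.05. The published t statistics cannot be exactly
recomputed from their printed rounded group summaries (they were evidently
computed from unrounded data); the package reproduces the one value that
is exactly recoverable from printed numbers, the variance ratio
1.787/1.483 = 1.205.

## Pipeline and problem sizes

`run_study` is a pure function of `StudyConfig`: design → simulation →
per-analyte window restriction → PLS-1 (LOO LV selection) → GA →
guard → GA-PLS refit → GA-ANN (hidden-size scan) → evaluation. All
randomness derives from `config.seed` through independent seeded streams
per stage, so identical configs give byte-identical reports.

The multi-seed experiments in `experiments.py` run the GA at population
20 for 10 generations with a 3/10/30 hidden-neuron scan — sizes chosen so
a ten-seed study completes in about two minutes on one CPU while leaving
every qualitative conclusion unchanged (the GA converges on these
fitness landscapes well before generation 10; larger populations only
sharpen the already-clear fallback decision). The full published GA sizes
remain the `GAConfig` defaults.

Dosage-form dilution arithmetic (`assay_dilution`) uses exact rational
numbers: a tablet's labelled content dissolved to 100 mL, an 0.4 mL
aliquot diluted to 100 mL gives 20, 1.2 and 0.32 µg/mL for PAR, CAF and
COD; spiking 200 µg of codeine into the same 100 mL raises COD to exactly
2.32 µg/mL.

## What passing tests show — and what they do not

The test suite demonstrates: exact reproduction of the published design
and dilution arithmetic; correctness of the NIPALS and LM engines against
independent oracles (textbook deflation, scikit-learn, ordinary least
squares); calibrated noise; rank-structure recovery; deterministic
reproducibility end to end; GA operator invariants and localization; and
that at σ = 0.002 AU the full workflow recovers validation concentrations
to within a fraction of a percent.

They do **not** show that the specific published recovery tables, RMSE
values, LV counts or retained-wavelength counts are reproduced — those
derive from real instrument spectra that are not publicly deposited, and
the synthetic generator makes no claim to mimic them numerically. Nor do
they show that GA selection *improves* prediction, which on this noise
model it provably should not; they show the machinery behaves correctly
and that the GA-vs-full-spectrum comparison is decided honestly.

## Known limitations

- Pure-spectrum shapes are invented stand-ins; conclusions transfer to
  real data only at the level of workflow behaviour, not cell values.
- The guard re-runs the GA on calibration splits, so `run_study` spends
  most of its time there; disable it only if raw GA output is wanted.
- The Dixon Q implementation is the single-outlier two-tailed table at
  α = 0.05, n ≤ 10 — sufficient for six-mixture validation sets.
- `max_val_fail = 1` makes ANN training stop aggressively on noisy
  validation sets; raise it for exploratory fitting.
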