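# Methods

This note documents the models, numerical choices and assumptions behind
`fgrscreen`, in the order the pipeline applies them.

## Scope and model of the assay

The package analyses linear-mode MALDI-ToF profile spectra of
affinity-enriched maternal serum proteins. The biological signal is the
relative abundance of five apolipoprotein C-II/C-III species; everything
else in a spectrum (≈55 further protein ion signals, chemical baseline,
detector noise, small mass-axis miscalibration) is nuisance structure the
preprocessing must be robust to. The assay's unit of measurement is an
*ion signal area* — the integral of intensity under a singly charged
protein peak — and all downstream quantities are ratios of such areas
within one spectrum, which removes the (large, uncontrolled) spectrum-wide
intensity scale.

## Synthetic cohort generator

Because cohort sera and raw spectra of this assay are not publicly
available, the package includes a first-class simulator whose role is to
realise the *statistical structure* the analysis assumes, so every stage
can be validated against known ground truth.

One spectrum is rendered per (patient, measurement series) on a regular
1 Da grid over m/z 4,000–20,000 as a sum of Gaussian ion signals (shared
width σ = 4 Da, a linear-ToF resolution scale) over an exponentially
decaying baseline (amplitude 10, decay scale 4,000 Da), plus additive
Gaussian noise (σ = 2 intensity units, clipped at zero) and a per-spectrum
affine mass-axis drift with slope error and (scaled) offset each uniform
within ±5·10⁻⁴ — small enough that calibrant signals stay inside the
±10 Da matching tolerance, as they must for an assay whose spectra are
externally calibrated before internal recalibration.

Signal content per spectrum:

* the five markers, the two calibrants (apoC-I, transthyretin), and
  53 background peaks placed uniformly at random, at least 50 Da away
  from every panel position so the desk-scale integration problem stays
  well-posed (no deconvolution is attempted, see Non-goals);
* background areas log-normal(ln 500, 0.8); calibrant areas
  log-normal(ln 3000, marker SD).

Marker areas are drawn log-normally — areas are positive and
right-skewed in MALDI profiling — per *patient*, with an additional
log-normal series-to-series jitter of SD 0.05 so replicates of one
patient resemble each other more than they resemble other patients.
Default log-means correspond to median areas (CTRL) of
8205: 2000, 8766: 1500, 8916: 5000, 9422: 300, 9713: 200 with a shared
log-SD of 0.2. The FGR effect multiplies the median of m/z 8916 by 3
(+ln 3 ≈ 5.5 log-SD) and of m/z 8766 by 2 (+ln 2 ≈ 3.5 log-SD), which
raises all three quotients jointly (expected quotients CTRL
A/B/C ≈ 2.5/3.0/2.5 vs FGR ≈ 7.5/6.0/4.3 — the same order of magnitude as
the published cut-off values). SGA patients are drawn from the CTRL
distribution, reflecting that constitutionally small fetuses are
biochemically unremarkable. No distributional parameters for cohort ion
signal areas are published; these defaults are documented assumptions,
not estimates of any real cohort.

Two QC artifacts can be injected, each assigned per patient (every
replicate of an affected patient carries it, as with real sera): serum
amyloid A1 contamination — extra peaks at m/z 11,527.0 / 11,683.5 with
apexes three times the tallest marker apex — and calibration failure,
realised as suppression of both calibrant signals.

What the simulator deliberately does **not** model: isotope envelopes,
adducts and matrix clusters, detector saturation, heteroscedastic
(intensity-dependent) noise, peak-shape asymmetry, gestational-age or
clinical covariates. Passing tests therefore demonstrate correctness of
the *analysis procedure* under the stated statistical assumptions, not
instrument-level realism.

## Preprocessing

**Recalibration.** The apex nearest each calibrant reference mass within
±10 Da is located; the unique affine map sending the two observed apexes
to 6631.6 and 13,762.4 Da is applied to the whole axis. The model is
strictly affine because two points determine exactly two parameters. A
missing calibrant, or |slope − 1| > 0.01 (an implausible stretch for an
externally pre-calibrated instrument), raises a calibration error and the
spectrum is excluded. Recalibration is idempotent to ~10⁻⁶ in slope.

**Peak detection.** A signal counts as present when the integrated excess
of intensity over the chord between the window edges exceeds five times
its expected noise level. The per-point noise is estimated robustly from
the median absolute successive difference over the *whole* spectrum
(peaks occupy a small fraction of a profile spectrum, so the median sees
the noise floor); integrating pools signal across the window, so low
peaks well under any single noise spike remain detectable while flat,
baseline-only and pure-noise windows are rejected. The detection window is
re-centred on the apex so drifted signals near the matching-window edge
are not cut by the chord. The statistic is a ratio of intensities and thus
invariant under uniform intensity scaling.

**Integration.** Apex = grid maximum within the matching tolerance (no
sub-grid interpolation; a 1 Da grid is an order of magnitude finer than
the ±10 Da tolerance). Area = trapezoidal integral over target ± 25 Da
after subtracting the linear chord between the window-edge intensities,
clipped so the baseline-subtracted signal is non-negative. The ±25 Da
window captures ≥ 6σ of a σ = 4 Da peak (closed-form Gaussian recovery is
within 0.1%, tested to 1%); chord subtraction removes any locally linear
baseline exactly and the simulator's exponential baseline to well within
1%. The integration dialect of the commercial software originally used
for this assay is proprietary; this explicit, configurable stand-in
(window, baseline mode, tolerance are all parameters) is the package's
own definition of the area measurement.

**QC.** A spectrum is excluded as SAA-contaminated when the apex
intensity at *both* serum amyloid A1 positions exceeds twice the median
marker apex (a ratio, hence scale-invariant); it is excluded as
uncalibratable when recalibration raised. Exclusions always carry a
machine-readable reason (`exclude_saa`, `exclude_calibration`).

## Cut-off training

The Youden scan ranks the pooled training values of one quotient, appends
sentinels min − 1 and max + 1 (the printed rule uses the absolute
constant 1, not a scale-relative offset), and evaluates candidates at the
midpoints of neighbouring values — "linear interpolation between
neighbours" realised at the symmetric fraction 0.5. The direction is fixed
globally (value > cut-off ⇒ FGR-positive) because FGR quotients run high;
the scan does not auto-detect orientation, so a pathological inverted
input yields Jmax ≈ 0 rather than a silently flipped classifier. Ties in
J are broken toward the smallest candidate, favouring sensitivity — the
clinically conservative choice for a screening assay. The scan returns the
full audit table (counts, sensitivity, specificity, J per candidate).
Equivalence with a brute-force classify-at-every-threshold oracle is
asserted in the tests over randomized lists with ties.

Two trained sets combine per quotient into (min, max) pairs; equal values
would collapse the middle regime and raise a degeneracy error. The
published sets "O" (4.2/5.0/4.0) and "W" (3.4/7.0/5.1) ship as presets,
and their combination as `paper_OW`.

## Scoring and aggregation

Boundary semantics are exactly as specified for the assay and are applied
to raw floats with no epsilon: "below or equal" scores low; only strictly
"higher than" scores high. Single mode: 0/1. Dual mode: 0.0 / 0.5 / 1.0
across the three regimes. The cumulative score (0–3) is compared with the
discriminator 1.0 — a configuration constant, not a trained quantity;
spectra at exactly 1.0 are CTRL.

Patients are consolidated by unanimity over their non-excluded replicate
spectra; any disagreement yields `indeterminate`, and indeterminate
patients are excluded from confusion statistics. Unanimity is the only
aggregation rule consistent with whole patients being dropped for
"indeterminate results"; majority or mean-score rules would always
produce a definite call.

## Evaluation

Confusion rates follow the standard definitions; zero-denominator rates
are NaN (serialized as null/empty), never 0. Reported values are rounded
half-up to 2 decimals, raw values retained. AUC uses the tie-aware rank
(Mann-Whitney) formulation on cumulative scores — a graded statistic is
required because the score distribution, not the binary call, carries the
ranking information; tests assert exact agreement with the all-pairs
probability definition. The power analysis uses the closed-form normal
approximation n = ⌈2 (z₁₋α/2 + z_power)² / d²⌉ per group (α = 0.05
two-sided, power 0.80 by default); it differs from the noncentral-t
iteration of dedicated power software by at most about one unit of n at
moderate effect sizes.

## Pipeline layout and problem sizes

An end-to-end run mirrors the intended study design: series MS1 of the
CTRL and FGR patients is the training set; every other spectrum (later
series plus all SGA spectra) is the test set. In dual mode the freshly
trained cut-offs are combined with preset "W". All artifacts are CSV/JSON
and byte-reproducible under a fixed seed: all randomness flows through
one seeded generator threaded through the stages.

Tests and the validation workloads use cohorts of 30–60 spectra per run
(e.g. 15 + 15 patients × 2 series for generalization checks) — sizes
chosen to match the scale of the clinical cohorts the procedure targets
while keeping the suite fast; at these sizes the default group separation
yields test-set sensitivity/specificity ≥ 0.9 and AUC ≥ 0.95, and label
permutation collapses Jmax to chance level (≈ 0.1–0.3 at n = 14 + 14,
reflecting the maximum-over-candidates bias at small n rather than real
signal).

## Known limitations

* The integration stand-in is not a reimplementation of any commercial
  peak-quantification dialect; absolute areas are not comparable across
  software, though the quotients are far less sensitive to the dialect.
* Cut-offs are trained independently per quotient (as the assay
  prescribes); no multivariable threshold optimization is attempted.
* The simulator's homoscedastic noise and symmetric Gaussian peaks are
  idealisations; real linear-mode spectra show mass-dependent width and
  intensity-dependent noise.
* No confidence intervals on AUC or the confusion rates are computed.
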