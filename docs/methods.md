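# Methods

This note records the modeling choices behind `rhizosense`: what is assumed,
which parameters matter, what the synthetic data do and do not emulate, and
where the design was genuinely open.

## Signal chain

An uptake experiment is a single-channel impedance recording (magnitude at a
fixed 2 kHz excitation) of a paper disc carrying seedlings.  After at least
3 h of rest, a small volume of salt solution (30 µL, 0.1 M in the default
design) is added; the analysis chain is

1. **Calibration** — per-salt log–log line `log10 Z = a + b·log10 c`, OLS on
   the supplied (c, Z) points.  The user selects the points in the linear
   range; no automatic breakpoint detection is attempted.  Inversion is the
   exact algebraic inverse; concentrations outside the fitted range are
   returned but flagged as extrapolation.  pH (open-circuit potential) and
   H2O2 (amperometric current) channels are plain linear maps
   `output = gain·input + offset`; their coefficients are user- or
   simulator-supplied since the devices vary piece to piece.
2. **Baseline** — arithmetic mean of all raw concentration samples in the
   first 2 h (default `baseline_window_hours = 2`).  Traces shorter than the
   window are an error, never silently truncated.
3. **Peak** — argmax of the concentration at `t ≥ t_add`, ties resolved to
   the earliest time.  If the post-addition series never exceeds the
   baseline, there is no peak and uptake is zero.
4. **Fit window** — from the peak to the first sample at which the trace has
   fallen to `baseline·(1 + tolerance)` (default tolerance 0.05, applied
   one-sided from above since additions raise concentration), else to the end
   of the recording with `reached_baseline = False`.  The crossing is read
   off the measured (smoothed) trace, not off an iteratively refitted curve —
   the fixed-point alternative is not well defined and was rejected.
5. **Power law** — `c = B·τ^k` with `τ = t − t_add`, fitted by OLS on
   `(log10 τ, log10 c)`.  `c = B·t^k` is origin-sensitive and the addition is
   the only physically distinguished instant, so the addition is the default
   origin (`t_origin = "addition"`, switchable to the detected peak).  A
   nonlinear least-squares refinement in linear space is available
   (`fit_method = "nonlinear"`) but the log-space OLS is the deterministic
   default.  k is stored signed (negative for decay); a constant window
   yields k = 0 exactly.
6. **Normalization** — `ratio = k_uptake / mean(k_control)` over the
   condition's plant-free controls, which are processed by the identical
   pipeline.  |mean control k| below `control_epsilon` (1e-9) flags the ratio
   undefined rather than emitting an infinity.  Ratios ≤ 1 are interpreted as
   net zero or negative uptake.

**Smoothing.**  Display, peak detection and window detection use a centered
rolling percentile filter counted in samples (default 50th percentile,
100-point window — the window used for smoothing uptake traces; the generic
`SmoothingSpec` default is 30 points).  Edge windows shrink to the available
samples, so output length and time base equal the input.  Whether the
original protocol smoothed before fitting is not documented; here the fit
runs on raw concentrations by default (`fit_on_smoothed = False`) and both
paths are available.  Even window counts are accepted (the published figure
smoothing used 30- and 100-point windows); the centering convention is
(w−1)//2 points left, w//2 right.

**Zero-uptake rule.**  A trace whose post-addition concentration never
exceeds baseline, never decreases, or peaks only at the final sample carries
no decay information: `k_uptake = 0`, `zero_uptake = True`.

## Group statistics

Categories: cations are macronutrients (K⁺, NH₄⁺), secondary nutrients
(Ca²⁺, Mg²⁺), sodium, or heavy metals (Ag⁺, Ba²⁺, Cd²⁺, Cu²⁺, Gd³⁺, La³⁺,
Ni²⁺); anions are macronutrients (NO₃⁻, phosphates), secondary nutrients
(SO₄²⁻), micronutrients (Cl⁻), or neutral (CO₃²⁻, OH⁻).  One-way
fixed-effects ANOVA uses the classical mean-square ratio with (g−1, n−g)
degrees of freedom; all-identical data make F undefined (flagged).  The post
hoc test is Tukey–Kramer: `q = |mᵢ−mⱼ| / sqrt(MSW/2·(1/nᵢ+1/nⱼ))` against
the studentized range distribution (scipy's numerical quantiles, so any
group count works; no printed tables).  With equal n the Kramer standard
error reduces exactly to the classical Tukey one.  Compact letters come from
the standard insert-and-absorb construction; letter order follows descending
group means.  Group summaries report mean, t-based 95 % CI, n, and letter.

## Range classification

Salt descriptors are deterministic functions of the formula: ion identities,
charges, stoichiometric counts, ionic and salt molar masses, periodic-table
group of the (central) element, and nutrient class of each ion.  The bundled
reference table covers the 29-salt calibration panel; unknown ions raise an
error naming the fragment.  Binning of normalized ratios: two ranges split at
ratio = 1 (uptake vs no uptake); 3–6 ranges keep the first boundary at 1 and
divide (1, max] into equal widths, top bin right-closed — a fixed,
deterministic rule, overridable by an explicit boundary list.  The classifier
is a gradient-boosted tree ensemble (depth 3, 100 rounds, learning rate 0.3,
single-thread, fixed seed; all overridable) under seeded 5-fold
cross-validation, stratified when every class has at least `n_folds`
members.  F1 is computed from the per-fold confusion matrix with the
0/0 → 0 convention: the plain two-class formula for binary labels, otherwise
the macro average over classes (skipping classes absent from both axes), then
averaged over folds.  Folds whose training part lacks a class are reported as
degenerate rather than silently accepted.  Whether the published score was
macro-, micro- or weighted-averaged is not documented; macro is this
package's stated convention.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:

- flat pre-addition concentration `c0` (default 1e-4 M residual background)
  for at least 3 h (`t_add = 3 h`);
- a step to `c_peak` (default 1e-2 M, a 30 µL addition of 0.1 M salt into a
  ~300 µL disc) followed by `c = c_peak·(τ/τ₁)^k_true`, anchored at the
  first sample strictly after the addition (τ₁ = one sampling interval) —
  this avoids the τ = 0 singularity and makes the first post-addition sample
  exactly `c_peak`; the decay floors at `c0`;
- impedance via the forward calibration map **plus** linear drift
  (default 100 Ω/h, the magnitude observed on plant-free discs) and
  multiplicative lognormal noise (default σ = 0.5 %).  Drift lives in
  impedance space (an electrode artifact), uptake in concentration space —
  this separation is what makes control normalization meaningful;
- 24 h of recording at 30 s sampling;
- a synthetic per-salt calibration (slope −0.5, ~1.6 kΩ at 1 M) placing
  post-addition discs near 16 kΩ and the pre-addition background near
  160 kΩ, matching the impedance levels of the instrument the design
  emulates.

Controls are generated with `k_true = 0`; their apparent concentration decays
slowly as drift raises the impedance, so the fitted control exponent is small
and negative (≈ −0.06 under the defaults), as the normalization logic
requires.

**Closed-loop cohort calibration.**  `generate_cohort` takes target
normalized ratios (e.g. the blocker-experiment presets 6.1 / 5.8 / 6.0 / 4.0
/ 4.7 / 3.1) and chooses each condition's `k_true` so that the *full
pipeline*, run on traces generated under the cohort's own noise settings,
recovers the target.  The first-order guess `k_true = target ×
k_control_eff` is refined by a secant iteration because (a) plant traces
also carry the drift, and (b) the fit-window start the pipeline selects
(argmax of the smoothed trace) differs systematically between noiseless and
noisy traces while the fitted control exponent is sensitive to that start —
under noise the control-equivalent exponent is therefore measured as the
mean over three internal seeded replicates.  This makes the generator's
contract exact: the emitted cohort, analyzed by the pipeline, reproduces the
targets (to ≲1e-3 noiseless, ≲0.2 at default noise with 4+4 replicates).

**ML datasets** draw salts (with replacement) from the bundled panel and
assign latent ratios from class-conditional normals whose means are pulled
away from a common center (3.5) in proportion to `class_signal_strength`
(heavy-metal cations near 1, nutrient cations near 5–6 at unit strength,
σ = 0.8) — the nutrient-high / heavy-metal-low pattern.  Strength 0 removes
all feature–label association; labels come from the same binning rule as the
real pipeline.

**What the generator does not emulate:** electrode physics (double layers,
diffusion profiles, response-time transients), biological replicate
structure (plant-to-plant variance, age and count effects), pH/H2O2 dynamic
responses, or correlated/heteroscedastic instrument noise.  Passing tests
therefore demonstrate correctness of the analysis chain and its estimators
under the assumed signal model, not robustness to every artifact of real
recordings.

## Numerical choices and degenerate inputs

- All logarithms are base 10.  OLS fits use `scipy.stats.linregress`; exact
  two-point calibration fits pin r² = 1.
- Power-law fits require ≥ 3 samples, strictly positive concentrations, and
  strictly positive τ; samples exactly at the origin are excluded.
- The percentile filter interpolates ranks linearly (numpy convention); the
  test suite checks it against an independent sort-and-interpolate oracle.
- Near-zero control means, zero-variance ANOVA inputs, empty manifests,
  unknown salts and ill-formed trace files all raise typed errors or set
  explicit flags; nothing degrades silently.
- Trace files are written with fixed `%.12g` formatting, so equal records
  produce byte-identical files and seeded runs are reproducible end to end.

## Problem sizes used in the checks

The bundled acceptance checks run on: 4 noiseless + 200 noisy traces
(2 880 samples each) for parameter recovery; 6-condition cohorts with 1+1
(noiseless) and 4+4 (noisy) replicates; 1 000 random instances for the OLS
oracles and ~120 series (length ≤ 200, window ≤ 15) for the filter oracle;
100 constructed zero-uptake cases; 10 000 null ANOVA replicates (4 groups of
8); and 20-seed cross-validation sweeps on 100–200-sample datasets.  These
sizes give stable statistics while keeping the whole suite fast on a single
CPU.

## Known limitations

- The fitted control exponent depends on where the detected peak lands; this
  is inherent to fitting a non-power-law drift decay in log-time and is the
  reason cohort calibration is closed-loop (see above).
- The uneven units in some published calibration ranges (mM-range lists vs
  an extended 0.01 µM–0.1 M range) are accepted as given; the module takes
  any positive range.
- The exact descriptor list used in the original classifier is not public;
  the feature schema here is a documented superset built from standard ion
  properties.
- Printed headline statistics of the original study (specific F values,
  F1 = 0.949/0.555) derive from raw data that are not deposited and are not
  reproduction targets; the package reproduces the machinery and its
  qualitative behavior (e.g. F1 decreasing with range count).
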