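# Methods

This note documents the models, numerical conventions and design
choices behind `emgfatigue`, and what the synthetic-data generators do
and do not emulate.

## Signal model and processing chain

A recording is a set of up to six surface-EMG channels (µV) sampled at
a common rate (default 2000 Hz), labeled by lumbar level and side
(`L1_left` … `L5_right`). The analysis chain is:

1. **Band-pass filter** — 4th-order Butterworth, 20–500 Hz, applied
   forward–backward (`sosfiltfilt`), so the response is zero-phase and
   the effective roll-off 8th-order. Zero phase matters because epoch
   timestamps feed a regression against time. A 50 Hz notch is
   available but off by default. Parameters: `filter.low_hz` (20),
   `filter.high_hz` (500), `filter.order` (4).

2. **Artefact screen** — samples with |amplitude| above
   `artifact.amplitude_uv` (3000 µV) are masked, as are runs of ≥
   `min_run` (5) identical samples at ≥ `clip_fraction` (0.95) of the
   channel's own maximum |amplitude| (AD-converter saturation; tying
   the threshold to the channel's own extreme catches full-scale
   plateaus whatever the absolute scale, and is sign-flip invariant).
   An epoch with more than `max_bad_fraction` (0.10) masked samples is
   excluded from the MF series; excluded epochs are flagged, never
   interpolated — fabricating spectra for corrupted intervals would
   bias the slope toward whatever the interpolant assumes.

3. **Epoching** — 500 ms epochs, Blackman taper, starting at
   `t_start` = 3 s (the stabilization interval is omitted) and
   advancing by `epoch_length × (1 − overlap)`; only epochs entirely
   inside [t_start, t_end] are used. The default advance is one full
   epoch (overlap 0), i.e. a step of 0.5 s, which yields the protocol's
   published output geometry: 27 s of MF data at 2 Hz, exactly 54
   values per channel of a 30 s recording. Descriptions of this
   protocol also mention 50 % epoch overlap, which is arithmetically
   incompatible with a 2 Hz / 54-sample series (it gives 4 Hz / 107
   epochs); this package treats the printed output geometry as the
   binding convention and keeps `overlap` a free parameter. Epoch
   timestamps are epoch centers, which makes the regression intercept
   interpretable midway into the first epoch.

4. **Spectrum** — per epoch: mean removal, Blackman taper, one-sided
   periodogram (density scaling), resolution fs/N = 2 Hz at defaults.
   No Welch sub-averaging inside an epoch: each epoch is transformed
   once. The documented normalization: total one-sided power
   `Σ S·Δf` equals `Σ(w·x_c)²/Σw²`, the tapered mean-removed epoch's
   power divided by the window's power normalization (verified to
   1e-6 relative in the tests).

5. **Median frequency** — integration band 20–450 Hz by default (the
   sensor hardware bandwidth; the digital filter passes to 500 Hz but
   no physiological power lies above the hardware band; configurable
   via `mf.band_low_hz`/`mf.band_high_hz`). Each bin is treated as a
   uniform cell of width Δf centered on its bin frequency; MF is the
   half-power crossing point, linearly interpolated inside the crossing
   cell; an exact tie at a cell edge resolves to the lower frequency.
   Zero in-band power makes the MF undefined and excludes the epoch.

6. **Fatigue regression** — per channel, OLS of MF against time over
   non-excluded epochs (minimum 10 points; channels with more than half
   their epochs excluded are refused). IMF is the fitted value at
   t_start — the onset of the regression window — not an extrapolation
   to t = 0 (available by flag). Normalized slope = 100·slope/IMF; at
   IMF near 100 Hz the Hz/s and %/s columns are numerically close by
   construction. No robust regression: the protocol specifies plain
   linear regression.

7. **Aggregation** — per-level bilateral means, all-electrode mean,
   and the most-negative electrode (minimum slope in Hz/s), re-selected
   independently per recording; ties break by the fixed channel order
   toward the caudal/right channel, for determinism.

## Imbalance scores

The per-level ratio series uses only epochs where both sides are
usable (pairwise alignment). The symmetric transform is the piecewise
reciprocal R(r) = r − 1 (r ≥ 1), 1 − 1/r (r < 1): antisymmetric,
centered at 0, and directly readable as the fractional excess of the
dominant side. The exact transform used by earlier imbalance work is
not recoverable from the available description, so the transform is an
explicit package convention: a log-ratio alternative (R = ln r) is
selectable, and every output records which transform produced it.
Global scores: uncompensated = mean |segmental| over L1/L2/L5,
compensated = signed mean, so uncompensated ≥ |compensated| always,
with equality when all levels lean the same way.

## Reliability model

Observed outcomes y_ijk over subject i, day j, side k follow the
crossed random model

    y = μ + s_i + d_j + l_k + (sd)_ij + (sl)_ik + e_ijk,

the five named error sources of the measurement design plus a residual
that confounds day×side, the three-way term, and pure error. Two
estimators:

* **ANOVA expected mean squares** (`anova_ems`) — closed-form solution
  of the balanced crossed design; negative estimates are truncated to
  zero and flagged (standard G-study practice, kept transparent rather
  than re-fitted). Exact on balanced data; used as the oracle.
* **REML** (`reml`, default) — direct maximization of the profiled
  restricted likelihood over log-variances (L-BFGS-B, dense Cholesky
  solves). Written in-package because no installed library fits fully
  crossed variance-component models of this shape; it handles the
  unbalanced designs real cohorts produce (dropouts). On balanced data
  it agrees with the closed form to well under 5 % per component.

Side-aggregated outcomes (all-electrode mean, most-negative electrode)
carry one value per subject × day, so their G-study is the one-facet
subject × day design, in which subject×day is confounded with the
residual and the side terms vanish.

Decision study: defaults n'_d = 1, n'_s = 2 — a score measured on a
single day as the bilateral mean, matching how per-day outcomes are
formed. D = σ²_subject/(σ²_subject + σ²_abs); SEM = √σ²_abs in outcome
units; qualitative labels follow ICC conventions (0.4–0.6 moderate,
0.6–0.75 good, >0.75 excellent). D̂ inherits substantial sampling
noise from the subject-variance estimate (relative sd √(2/(n_subj−1)));
at 40 subjects its sd is ≈ 0.05 even for well-chosen designs — worth
remembering when comparing dependability values between small groups.

## Cohort statistics

Type II sums of squares for the two-way age × gender ANOVA: the 2×2
design is unbalanced in realistic cohorts and type II tests each main
effect adjusted for the other without imposing an interaction-weighted
weighting. Analyses run on per-subject values averaged over test days
(primary) or restricted to one day. Bootstrap contrasts: stratified
resampling within factor level, percentile intervals, B = 2000, seeded
explicitly; reported as young − old and male − female. Percentile
intervals undercover slightly at small group sizes (~93 % at n = 40
per group, ~94–95 % at n = 80); the coverage checks in the test suite
use n = 80. Shapiro–Wilk is advisory only and never gates the
pipeline.

## Synthetic data

**EMG generator.** The contract is exact spectral ground truth, not
biophysical realism. The per-channel spectral template is a two-scale
shape: a narrowband line carrying `carrier_fraction` (0.5) of the
power at the commanded median frequency, plus Gaussian shoulders
(`shoulder_width` 25 Hz) truncated to the analysis band. Because the
line straddles the half-power point, the template's median equals the
line frequency exactly (closed form via the truncated-normal CDF; a
root-finder relocates the center in the degenerate truncation cases).
The line is realized as a frequency-modulated cosine whose
instantaneous frequency is the commanded trajectory
MF(t) = imf0 + slope·(t − 3 s); the shoulders are random-phase shaped
Gaussian noise synthesized in 250 ms piecewise-stationary blocks,
crossfaded by √Hann overlap-add. All draws come from one seeded
generator per call; identical spec + seed is bit-identical.

What this does and does not show: the concentrated template keeps the
per-epoch MF estimation noise below ~1 Hz, so the recovery tests
demonstrate the *pipeline's* correctness (geometry, estimator algebra,
regression) at tight tolerances — IMF to ±2 Hz and slope to
±0.05 Hz/s per recording. Real surface EMG has a much flatter spectrum
whose 500 ms periodogram median scatters by several Hz epoch-to-epoch;
slope estimates from real 27 s contractions are correspondingly
noisier, and the tight synthetic tolerances must not be read as
real-data accuracy. Motor-unit structure, amplitude nonstationarity
and electrode artifacts beyond simple spikes/plateaus are not
emulated. Adjacent epochs share synthesis blocks, so MF values are
weakly autocorrelated and OLS standard errors are mildly
anticonservative (null-slope 95 % CIs cover ~90 %).

**G-study generator.** Direct draws from the crossed random model at
specified variance components; balanced by construction. The default
components (subject 25, day 1, side 0.5, s×d 2, s×s 1, residual 5, in
Hz² for an IMF-like outcome) put most variance between subjects with
modest day/side effects, the regime a standardized seated protocol
aims for. For dependability-recovery experiments at true D = 0.80 the
mix (day 0.2, side 0.1, s×d 2.5, s×s 1.2, residual 5.8) concentrates
error variance in the high-df facets, since the day (df = n_d − 1) and
side (df = 1) main-effect estimates are the noisiest parts of the
decision-study error.

**Cohort generator.** Per-subject outcomes drawn normal with cell
means = base + age effect + gender effect (+ interaction); default
cohort structure 44 young (19 women) / 42 old (21 women), ages uniform
within 18–49 and 50–90, dichotomized at 50 years. Default effect sizes
emulate the published magnitudes of 80 %-MVC back-extension testing:
higher L5 IMF and flatter (less negative) fatigue slopes in the older
group, e.g. an L5 slope of −0.24 (young) vs −0.14 Hz/s (old) with a
residual sd of ~0.23 — a moderate effect that borderline-significant
cohorts of this size resolve with roughly 50 % power.

## Numerical and degenerate-input conventions

* Sampling rate comes from the time column (median Δt) with a 1 ppm
  uniformity requirement — a hard error, not a warning, because every
  spectral quantity scales with fs. An explicit override is available.
* Median-frequency ties resolve to the lower frequency; results are
  clamped to the integration band.
* All-zero epochs produce zero spectra and are excluded (undefined MF)
  rather than propagated as NaN.
* Variance-component truncation at zero is flagged in the result; the
  REML optimizer works on log-variances with a floor of 1e-10 × the
  outcome variance, and components below 1e-6 × the outcome variance
  report as exact zeros.
* Degenerate statistics raise typed errors: constant outcomes in the
  ANOVA, zero-variance samples in the normality check, single-subject
  or single-day reliability designs, empty ANOVA cells.

## Known limitations

* The spectral generator is a calibration instrument, not an EMG
  simulator; see above for what recovery tolerances do not imply.
* The ANOVA-EMS estimator requires strictly balanced designs; REML
  covers the rest but assumes Gaussian components.
* The reliability model omits a day×side interaction by design
  (confounded into the residual); data with a genuine day×side effect
  will inflate the residual.
* No nonlinear (exponential/piecewise) fatigue models, no endurance-
  time prediction, no amplitude-based asymmetry indices, no vendor
  binary formats (delimited text only).
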