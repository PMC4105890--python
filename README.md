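# emgfatigue

Median-frequency (MF) surface-EMG fatigue analysis for the lumbar back
extensors: a tested, reusable implementation of the spectral fatigue
protocol used to screen for sarcopenic back-muscle alterations, with a
biostatistics layer for retest reliability and group comparison.

## Who this is for

Researchers and clinical scientists who record multi-channel surface
EMG during sustained isometric back extensions (bilateral electrodes at
the L1 iliocostalis lumborum, L2 longissimus and L5 multifidus sites,
typically 30 s at 80 % MVC, sampled at 2000 Hz) and want the standard
spectral fatigue descriptors, their left–right imbalance scores, and
defensible reliability statistics — without re-deriving the signal
processing each time.

## What it computes

**Spectral fatigue descriptors.** Each channel is band-pass filtered
(20–500 Hz, zero-phase Butterworth), screened for artefacts, and cut
into 500 ms Blackman-tapered epochs after omitting the first 3 s of the
contraction; each epoch's one-sided periodogram yields the median
frequency — the frequency f* splitting the in-band spectral power into
equal halves,

    ∫_lo^f* S(f) df = ∫_f*^hi S(f) df,

giving 27 s of MF data at 2 Hz (54 values per channel). An ordinary
least-squares line MF(t) = a + b·t over those points gives

* **IMF** — initial median frequency, the fitted value at the 3 s
  analysis onset (Hz), a proxy for muscle-fiber composition;
* **MF slope** — b (Hz/s), the spectral fatigue rate;
* **normalized slope** — 100·b/IMF (%/s).

Outcomes are aggregated as bilateral per-level means, the all-electrode
mean, and the most-negative (steepest-declining) electrode.

**Bilateral imbalance.** Per level, the epoch-by-epoch ratio
r = MF_right/MF_left is mapped through an antisymmetric transform
(R(r) = r − 1 for r ≥ 1, 1 − 1/r otherwise; R(1) = 0, R(r) = −R(1/r));
100 × the mean R is the signed segmental imbalance (%). Across the
three levels, the **uncompensated** score is the mean absolute
segmental value and the **compensated** score the signed mean.

**Retest reliability (G-theory).** Outcomes measured over subjects ×
days × sides are decomposed into variance components (subject, day,
side, subject×day, subject×side, residual) by closed-form ANOVA
expected mean squares (balanced designs) or REML (unbalanced). A
decision study averaging over n'_d days and n'_s sides gives the
absolute error variance

    σ²_abs = σ²_d/n'_d + σ²_l/n'_s + σ²_sd/n'_d + σ²_sl/n'_s + σ²_e/(n'_d·n'_s),

the dependability coefficient **D = σ²_subject/(σ²_subject + σ²_abs)**
(the ICC-type index for absolute, criterion-referenced decisions) and
the absolute **SEM = √σ²_abs**.

**Cohort statistics.** Two-way age (<50 vs ≥50 years) × gender ANOVA
(type II sums of squares) plus stratified percentile-bootstrap
confidence intervals for the group mean differences; Shapiro–Wilk as an
advisory normality diagnostic.

**Synthetic data.** Generators for every input with exact ground truth:
fatiguing EMG recordings whose instantaneous median frequency follows a
commanded linear trajectory (FM carrier + shaped-noise shoulders),
balanced subject×day×side datasets with specified variance components,
and age×gender cohorts with specified effects.

## Worked example

```bash
python examples/01_fatigue_analysis.py
```

```
MF series: 54 values per channel at 2 Hz over [3, 30] s
channel     IMF (Hz)  slope (Hz/s)  norm (%/s)    R^2
L1_left        99.92        -0.295      -0.295  0.967
L1_right       99.94        -0.287      -0.287  0.954
L2_left       100.10        -0.307      -0.306  0.960
L2_right       99.97        -0.290      -0.290  0.921
L5_left       100.01        -0.305      -0.305  0.955
L5_right      100.18        -0.305      -0.305  0.967
all (mean)    100.02        -0.298      -0.298
most negative electrode: L2_left (-0.307 Hz/s)
```

The simulated contraction had a true IMF of 100 Hz declining at
−0.30 Hz/s on every channel; the pipeline recovers the IMF to a
fraction of a Hz and the slope to a few thousandths of a Hz/s. The
other example scripts cover bilateral imbalance (`02`), G-theory
reliability (`03`), the age×gender cohort comparison (`04`) and the
batch manifest pipeline with a reliability report (`05`). A thin CLI
(`emgfatigue fatigue|reliability|cohort|simulate-*`) wraps the same
functions for shell use.

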