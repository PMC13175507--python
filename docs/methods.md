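# Methods

This note documents the models, conventions and numerical choices behind
`flickervig`, and what the synthetic-data generator does and does not
emulate.

## Study design being analyzed

Three arms of healthy adults perform a psychomotor vigilance task for one
session while receiving 40 Hz audiovisual flicker, random (sham) flicker, or
constant light.  Scalp EEG (32-channel 10–20 montage) is recorded in a
baseline phase, an "occluded" phase (eyes and ears blocked while stimulation
runs, to expose electrical artifacts), and the stimulation/task phase.  The
analysis asks whether 40 Hz flicker (i) entrains a steady-state response at
40 Hz, (ii) changes band power — in particular delta (2–4 Hz) — and
functional connectivity — in particular lower alpha (8–10 Hz) — during
attending periods, and (iii) improves accuracy and reaction time, with the
neural and behavioral changes correlated across subjects.

## Spectral conventions

- **Working rate 512 Hz.** The spectral parameters (2 s windows, 1024-point
  FFT) are mutually consistent only at 512 Hz, where one window is exactly
  1024 samples and the grid step is 0.5 Hz.  Recordings at other rates are
  polyphase-resampled once at ingest; the rate is a config knob.
- **Epochs** span −4 to 0 s relative to the color change (the attending
  period).  Epochs that cross a recording edge or a task break are dropped
  and logged, never silently.
- **Welch PSD**: Hamming-tapered 2 s segments at 50% overlap, no detrending
  (a zero-phase 1 Hz Butterworth high-pass runs upstream), one-sided density
  scaling so the integral over frequency approximates signal power.  Each 4 s
  epoch contributes 3 segments; segments are pooled across epochs.
- **Normalization** divides each channel's PSD by its own trapezoidal area
  over 2–55 Hz (1–55 Hz is the alternative first-class option, paired with a
  1–4 Hz delta definition).  Normalized spectra are scale-invariant per
  channel; the area over the normalization range is exactly 1.
- **Bands**: delta 2–4, theta 4–8, alpha 8–13, beta 13–30, low gamma
  30–37 Hz, the flicker-response band 39–41 Hz, and the alpha split into
  lower 8–10 / upper 10–13 Hz.  Band edges are half-open `[lo, hi)` with the
  top edge included only for the uppermost canonical band (and the flicker
  band), so every bin belongs to exactly one canonical band.  Band power
  defaults to the maximum bin ("peak power"); the band mean is available as
  a sensitivity option.
- **Aperiodic fit**: an iterative robust straight line in log10-power vs
  log10-frequency — initial least squares, mask bins whose residual exceeds
  +2.5 robust SD (median/MAD; candidate narrowband peaks), refit on the rest.
  The residual spectrum (observed minus fitted line) is the periodic
  component and may be negative.  This deliberately simplified model replaces
  a full Gaussian-peak spectral parameterization: the hypothesis tests run on
  normalized power, and the aperiodic fit serves separation and topographic
  visualization, where the line-plus-masking model recovers exponents within
  ±0.1 on peak-free 1/f input across exponents 0.5–2.  The fit needs ≥ 10
  unmasked bins.

## Flicker-response criterion

Per channel, z = (power at the 40 Hz bin − mean of flank bins) / SD of flank
bins, with flanks 31–39 and 41–49 Hz and the SD taken **across frequency
bins** of the trial-averaged spectrum (the criterion is defined on a single
spectrum; an across-trials SD would be a different statistic).  A channel is
modulated at z ≥ 3; a subject at ≥ 3 modulated channels including at least
one in each hemisphere (10–20 convention: odd suffix left, even right, `z`
midline; midline channels count toward the total but toward neither
hemisphere).  The criterion runs on raw power by default — it is scale-free
within a channel — with normalized input accepted.  The 40 Hz bin is the
exact grid bin at 0.5 Hz resolution; a ±0.5 Hz maximum mode exists for other
grids.  Channels flagged during the occluded phase mark the subject
artifact-suspect.

## WPLI and the permutation null

`WPLI_xy(f) = |E{Im S_xy(f)}| / E{|Im S_xy(f)|}`, the expectation running
over the same tapered 2 s segments as the Welch PSD, pooled across epochs (a
per-trial averaging option is not provided; pooling is the documented
convention).  When the denominator vanishes — identical signals, or purely
zero-lag coupling — WPLI is defined as 0; a machine-precision guard
(denominator below 1e−10 of the mean cross-spectral magnitude) applies the
same convention to numerically degenerate bins.  WPLI is symmetric in the
pair, invariant to per-channel amplitude scaling, and lies in [0, 1].

The null distribution pairs one uniformly random channel from each of two
distinct subjects drawn from the whole analyzed cohort (any groups): genuine
coupling cannot exist across subjects, while within-subject segment
structure is preserved.  Epochs are aligned by ordinal index and truncated
to the shorter subject.  Band scalars (the band **mean** by default; the
peak is also reported) are collected per permutation; thresholds are the
nearest-rank empirical percentile (99.99th by default — the maximum of
10,000 samples) per band, with a pooled-across-bands threshold also written.
Significance is strict inequality above the threshold.

Two finite-sample caveats the tests make explicit: the null needs enough
distinct subject × channel combinations to populate its tail (with few
subjects and channels the permutation distribution collapses onto a handful
of distinct values), and the WPLI estimator's spread shrinks roughly as the
inverse square root of the segment count, so fixtures meant to sit "at noise
level" should carry segment counts near the design's (hundreds per subject).

High-FC pair sets take the `quartile` (default 0.75) quantile — linear
interpolation — of band WPLI pooled across all groups' pairs and return, per
group, the pairs strictly above it.

## PVT scoring

A trial is **premature** if any press precedes the color change (the first
press governs even when a later press falls in the window), else a **hit**
if the first press lands in `(change, change + 1 s]`, else a **miss**.
Reaction times are recorded for hits only; presses after the window are
ignored for that trial and logged.  Accuracy = hits / trials; RT variability
is the sample SD of hit RTs (the coefficient of variation is an option).
Subjects with accuracy strictly below 80% are excluded from behavior
statistics (retained for EEG-only analyses by config).

## Statistics

Kruskal–Wallis omnibus tests; post-hoc two-sided rank-sum tests restricted
to the two hypothesis-driven pairs (40 Hz vs Light, 40 Hz vs Random) with
Benjamini–Hochberg FDR over exactly that family.  The rank-sum test uses
exact enumeration when both groups have n < 10 and no ties, otherwise the
tie-corrected normal approximation.  All-tied input returns H = 0, p = 1.
Spearman correlations carry explicit family sizes (15 for five bands × three
channels; 3 for the flicker band at three channels); constant features are
flagged, not reported as zero correlations.  Proportion tests are Pearson
chi-squared without continuity correction (Yates is exposed upstream via
scipy if wanted) with Cramér's V = sqrt(χ² / (n · (min(r,c) − 1))).
Per-channel difference maps use the unpaired two-sided t statistic (sign =
group 1 minus group 2) and are written for external topographic rendering;
zero-variance channels are flagged NaN.  Mixed ANOVAs are not
re-implemented; the statistics report is the attachment point for them.

## Synthetic-data generator

Each channel is one Gaussian process built by spectral shaping of white
noise, with one-sided PSD

```
P(f) = 10^offset / f^exponent  ×  band scalings
     + Σ_bands Gaussian bumps (center, bandwidth, RMS = amplitude/√2)
     + noise_sd²·(2/fs)
```

(defaults: offset 1.0, exponent 1.5, delta 3 Hz/amp 2, theta 6 Hz/1.5, alpha
10 Hz/3, beta 20 Hz/1, sensor noise SD 1, 512 Hz, 32-channel 10–20 montage).
Deterministic given the seed.  On top of the per-channel process:

- the steady-state flicker response is a sinusoid at 40 Hz (default
  amplitude 1, giving channel z-scores far above the detection threshold, as
  in responsive subjects);
- each coupled pair shares a band-limited latent source (2 Hz bandwidth)
  added to both channels, one copy Hilbert-phase-shifted by the configured
  lag, with amplitude = strength × 3 signal units — the expected WPLI
  direction and peak frequency are known by construction;
- `zero_lag_mix` m replaces each channel by (1−m)·own + m·common, the
  volume-conduction confound: coherence rises toward 1 while WPLI stays at
  noise level.

Task timing: attending periods uniform on 4.7–7.3 s, 0.2 s color change,
0.8 s post-change, 1 s response window, breaks (two 60 s pauses per hour by
default) skipped by the trial stream.  Responses follow a shifted lognormal
(median 0.35 s, shape 0.25, shift 0.1 s), misses occur with probability
0.04, premature presses as a Poisson process at 0.0015 /s during attending.
These values were set once so that control-arm accuracy sits in the
mid-90s% and the 40 Hz arm near 98%, with the 40 Hz arm's RT scale 0.887
(11.3% faster) — the magnitudes the design targets.

Cohorts draw per-subject parameters around group means with 10% lognormal
jitter.  A subject-level **arousal trait** (lognormal, log-SD 0.2) jointly
scales delta-band power (×a), miss probability (×a³) and median RT (×a^0.3):
drowsier subjects show more delta and perform worse.  This is what makes
delta power correlate with accuracy and RT **across** subjects (ρ ≈ −0.3 to
−0.6 at the default design), not merely between groups; the exponents are a
declared modeling choice, set once.  Group effects multiply on top: the
40 Hz arm has delta_power_scale 0.7 (applied to both the delta oscillation
and the aperiodic background within 2–4 Hz — the planted effect is a
band-limited power change, not a single peak), lower-alpha coupling scale
1.3, the flicker response switched on, rt_scale 0.887 and a −0.038 miss
offset.  The delta and coupling magnitudes encode the reported directions;
their sizes are the generator's declared conditions, not measured
quantities.

**What the generator does not emulate:** eye-blink/muscle artifacts and bad
channels (the pipeline accepts pre-cleaned data), head-model forward mixing
beyond the single zero-lag confound, SSVEP harmonics, realistic inter-subject
variability (real cohorts vary far more than 10–20% lognormal jitter),
non-stationarity within a session (fatigue drift), and the self-paced pacing
that makes real sessions contain fewer trials (~350/hour) than the stated
timing implies (~490/hour).  Passing tests therefore demonstrate that the
estimators and decision rules are implemented correctly and recover planted
structure at realistic SNR — not that effects of these sizes would be
detected in arbitrary real cohorts.

## Problem sizes and determinism

Tests and the default pipeline run at desk scale: sessions of ~100–410 s
(17–60 trials), 8–32 channels, permutation nulls of 100–2,000 samples
(10,000 is the analysis default), and 20-cohort recovery studies at the
design's group sizes (21/22/19).  Every stochastic stage receives a child
seed derived from one global seed (`numpy.random.SeedSequence`); identical
configs produce byte-identical output tables.

## Known limitations

- The aperiodic model has no explicit knee; spectra with a low-frequency
  knee bias the exponent.
- The permutation null aligns epochs by ordinal index; if two subjects'
  sessions differ grossly in structure the truncation discards data.
- WPLI at 0.5 Hz resolution cannot separate coupling closer than one bin;
  peak-frequency ties resolve to the lower frequency.
- The behavior model has one response channel; it cannot represent multiple
  rapid presses inside the response window as distinct strategies.
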