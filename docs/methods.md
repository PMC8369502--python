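# Methods

This note documents the models, conventions and numerical choices behind
`apscreen`: what the simulator emulates, how the waveform measurements are
defined, and where the design was genuinely open.

## 1. The simulated recording

A well's trace is

```
F(t) = baseline − drift·t + Σ_k A_k · w(t − τ_k) + ε(t)
```

where `w` is the calibrated single-beat template (peak-normalized), `τ_k`
are beat activation times, `A_k = A·max(1 − drift_rate·τ_k/60, 0.2)` applies
linear photobleaching to beat amplitude as well as to the baseline, and
`ε(t)` is i.i.d. Gaussian noise with standard deviation `noise_sd·A`.
Inter-beat intervals are `IBI·(1 + cv·z_k)` with standard normal `z_k`,
clipped to [0.6, 1.8]× the mean so extreme draws cannot overlap beats.

All randomness flows through three counter-based streams per well
(`SeedSequence((seed, k))`, k = 0 onsets / 1 noise / 2 events). Injecting an
event therefore changes only its own footprint: an arrest keeps the
identical baseline and noise, and an irregular injection with CV 0 is
bitwise identical to the uninjected trace.

### Beat waveform and calibration

The single beat is a logistic upstroke multiplied by a repolarization
profile built from three exponential decays plus a plateau sigmoid —
enough freedom for both plateau-bearing and spike-like morphologies. Shape
parameters are fit by bounded least squares so that the *measured* durations
of the noise-free beat (measured with exactly the routine the analysis
pipeline uses, on a 0.5-ms template grid) match the preset's APD targets;
a monotone PCHIP time-warp of the repolarization limb then removes the
residual, iterating with 0.5 damping until every target is hit to < 0.05 ms
(tolerance 1 ms; failure raises `CalibrationError` with the residuals).
The exponential family alone cannot interpolate seven arbitrary monotone
crossing times this tightly; the warp closes that gap while preserving the
family's overall morphology. The template tail is cosine-tapered to zero
over its last 40 ms.

Because generator and analyzer share one measurement routine, the
analysis-side conventions (activation reference, smoothing, crossing
estimator — §3) cancel out of the closed loop: measured durations equal the
targets by construction on clean data.

### Presets

Published plate-assay values for the two preparations are rate-corrected
(cAPD, Fridericia). Presets therefore accept corrected targets and store
uncorrected generation targets via the inversion
`APD = cAPD·(60/rate)^{1/3}`, so that the pipeline's corrected outputs land
back on the corrected values. The anchors (rate, cAPD20/50/90, and the
plateau width ratio) are the published subtype values; the intermediate
fractions are simulator calibration choices that realize the width ratios
while keeping the set monotone:

| parameter | CT (ventricular-like) | AM (atrial-like) |
|---|---|---|
| beat rate (/min) | 83.7 | 237 |
| cAPD20/30/40 (ms) | 159.8 / 221.8 / 254.3 | 69.8 / 84.8 / 96.8 |
| cAPD50/70/80/90 (ms) | 315.5 / 332.5 / 357.5 / 369.7 | 114.9 / 129.9 / 145.9 / 156.1 |
| width ratio (40−30)/(80−70) | 1.30 | 0.75 |
| upstroke time constant (ms) | 8 | 3 |
| noise_sd (fraction of amplitude) | 0.01 | 0.01 |
| drift (fraction of amplitude / min) | 0.03 | 0.03 |
| IBI jitter CV | 0.02 | 0.02 |

Noise of ~1% of beat amplitude reflects the high SNR of well-averaged
photometry (a whole-well photodetector integrates over thousands of cells);
the detectors are additionally validated at 5% noise. Drift of a few
percent per minute is typical mild photobleaching and exercises the
detrending stage.

### Plateau ratio convention

The plateau ratio is the **segment-width ratio** (APD40−APD30)/(APD80−APD70):
the time spent between 30 and 40% repolarization relative to the time spent
between 70 and 80%. A plateau slows early repolarization, making the ratio
exceed 1; spike-like cells repolarize fast early and slow late, pushing it
below 1. (A ratio of *mean durations*, mean(APD30,APD40)/mean(APD70,APD80),
is strictly < 1 for any monotone duration set and could never reach the
ventricular-like value of 1.30.) The ratio is invariant under Fridericia
correction. For a beat with a linear decay all widths are equal and the
ratio is exactly 1.

### Event injection

* **EAD** — an additive Gaussian deflection (SD 12 ms) on the
  repolarization limb at a target decay fraction. A deflection riding on a
  decaying limb loses part of its height to the local slope before it shows
  up as a local maximum, so the injected height is calibrated numerically
  such that the *realized secondary-maximum prominence* on the clean beat
  equals `bump_frac·amplitude` — the quantity a detector sees and the
  natural meaning of "an x% EAD". EADs are a plateau-morphology phenomenon:
  on the steep atrial-like decay a physiologic-sized deflection cannot form
  a local maximum at all, consistent with EADs being observed in the
  ventricular-like preparation.
* **Irregular** — the requested IBI CV is added in quadrature to the
  preset's own jitter, reusing the same normal draws; ground truth records
  the realized CV.
* **Arrest** — beats with activation at or after the onset time are removed;
  baseline, drift and noise are untouched. Onset 0 yields a beat-free trace.

## 2. Trace detrending and beat detection

Detrending subtracts a rolling 10th-percentile baseline over a window of 3×
the median beat period (fallback 2 s when no period is found; traces shorter
than one window pass through with a warning). Beat detection is two-pass:
a bootstrap pass with a prominence floor of 5× the robust noise SD
(estimated from median absolute first differences) establishes the median
beat amplitude and IBI; the definitive pass uses prominence ≥ 30% of the
median amplitude and a refractory lockout of 50% of the median IBI (floor
100 ms). If the candidate population's median prominence is below 10× the
noise SD the trace is declared beat-free — the arrest signature — which
keeps pure-noise traces from yielding spurious beats. Edge-clipped beats
(no baseline window before the upstroke, or repolarization truncated by the
trace end) are discarded.

## 3. Waveform measurement

* **Smoothing.** Level crossings and the activation estimate use a
  Savitzky-Golay smoothed copy (quadratic, 25-ms window, defined in time so
  5- and 10-ms recordings behave consistently). Amplitudes and slopes use
  the raw signal.
* **Activation** (PWD start reference) is the time of maximum upstroke
  velocity. The upstroke is first localized at the half-amplitude upward
  crossing of the smoothed signal (searching derivatives across a whole
  diastole latches onto noise spikes); within ±60 ms of it, the activation
  is the midpoint of the half-maximum crossings of the smoothed derivative —
  far more stable on a noisy, skewed velocity peak than the raw argmax. An
  upstroke unresolved at the sampling interval (an idealized step) is
  assigned the first sample at/after the jump, which makes the analytic
  triangle-beat cases exact.
* **Amplitude** = raw peak (searched only ±20 ms around the detected peak)
  minus the local diastolic baseline (median of the 50 ms preceding the
  upstroke foot).
* **Crossings.** PWD_x is the time from activation to the first downward
  crossing of `baseline + (1−x)·amplitude`. Candidates are located on the
  smoothed signal with a persistence check (median of the following 5
  samples must sit at/below the level) and then refined by a linear
  regression of the *raw* signal over a symmetric window of up to ±12 ms,
  clipped to half the distance to neighbouring crossings. Window centers
  come from the well-median crossing offsets rather than each beat's own
  candidate, so the window placement is independent of the beat's noise and
  the per-beat estimate is unbiased to first order — first-crossing times
  of noisy signals are otherwise systematically early, by tens of
  milliseconds on slow plateaus. Crossings never found before the next beat
  leave that PWD undefined; such beats are excluded from the affected means
  but still count toward the rate.
* **Slopes** are raw first differences divided by the sampling interval
  (maximum on the upstroke, minimum on the decay, the latter reported
  positive); normalized variants (s⁻¹, divided by amplitude) are also
  emitted since vendor conventions differ.
* **Fridericia correction** is applied per beat with that beat's own
  preceding IBI in seconds (`PWDcF = PWD/IBI^{1/3}`), then averaged; the
  first beat of a window has no preceding IBI and is excluded from
  corrected means. PWD30-80 is the corrected difference; the uncorrected
  difference is also emitted.
* **Summary window** is the first 30 s of each recording phase; beat rate
  is `(n−1)/(t_last−t_first)·60` for n ≥ 2.

## 4. Event classification

Thresholds (all config-exposed): EAD secondary-maximum prominence ≥ 5% of
beat amplitude with width ≥ 2 samples, searched between the 30% and 95%
decay levels; irregularity = IBI CV > 0.15 (scale-free across the ~3×
CT/AM rate difference), undefined below 5 beats; arrest = ≤ 1 beat per
window (tolerating one residual artifact peak). Priority arrest > EAD >
irregular > normal; exactly one label per well.

A single beat's EAD bump competes with noise at only a few sigma (a
matched-filter calculation for an 8% bump in 5% noise gives ≈ 3.7σ per
beat), so per-beat testing cannot reach high sensitivity and specificity
simultaneously. The EAD decision therefore pools beats: all beats are
aligned on activation and reduced to a median beat (noise ↓ ~√n), the
prominence rule is applied to that median beat, and positives are attributed
to individual beats by a confirmatory half-prominence check around the
ensemble bump position. Beats affected in only a small fraction of the well
are correspondingly harder to detect — a documented limitation.

## 5. Dose-response statistics

Percent change is `100·(post − pre)/pre` per well; wells with an undefined
pre-phase value (e.g. already arrested) are excluded with a logged reason,
never coerced to 0%. Arrested post wells contribute to incidence
denominators but not to parameter means (their durations are undefined).
Tables report mean ± SD (not SEM) with n = contributing wells.

Two-group comparisons: Shapiro-Wilk normality recorded per sample, variance
homogeneity gated by a two-sided F-ratio test at α = 0.05 (the gate itself
is a convention choice; exposed as a parameter), Student's t when
homogeneous, Welch's t otherwise. Three or more groups: one-way ANOVA with
Tukey HSD follow-up. No multiple-testing correction is applied across
parameters or concentrations beyond Tukey within a family.

## 6. Verification strategy and problem sizes

Everything is tested against either analytic oracles (a triangle beat with
instantaneous upstroke and linear decay makes every duration and slope
exact) or simulator ground truth. The standard problem sizes are 30-s
recordings at 5-ms sampling (~41 CT / ~118 AM beats per well); detector
operating characteristics use 120 wells with injected events at 5% noise;
the type-I error check uses 500 null two-group comparisons; calibration is
property-tested over randomized physiologic target sets (rates 40-250/min,
APD90 80-500 ms, inter-fraction gaps ≥ 8 ms — gaps below the smoothing
scale are not physiologic and not resolvable).

What passing tests show: the pipeline recovers its own generator's ground
truth and the published subtype values under the stated noise model. What
they do not show: performance on real recordings with 1/f noise, motion or
calcium-bleedthrough artifacts, APD restitution (beat-to-beat dependence of
duration on the preceding interval), cell-to-cell heterogeneity, or
contraction-uncoupling pharmacology — none of which the simulator models.
Well-to-well variability beyond rate jitter and noise is also not modelled,
so between-well SDs of synthetic plates are optimistic.

## 7. Known limitations

* The simulator's noise is white Gaussian; plate photometry also shows
  low-frequency components that the detrending stage only partially mimics.
* Hill-type effects scale parameters phenomenologically; there is no
  ion-channel model, so effect combinations that would interact
  biophysically (e.g. rate-dependent APD changes) are independent here.
* The EAD model is a single additive deflection per beat; real EADs can be
  multiple, voltage-dependent and self-perpetuating.
* Classification is per-window; time-resolved classification over a long
  post-compound recording (events early after application) is out of scope.
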