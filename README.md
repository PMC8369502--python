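# apscreen

Waveform analysis for high-throughput membrane-potential screening of human
iPS-cell-derived cardiomyocytes — plus a calibrated simulator of the
plate-format fluorescence recordings the analysis consumes.

Plate-imaging platforms record one voltage-dye fluorescence trace per well of
a 96-well plate. Cardiac safety screens compare the spontaneous action
potentials of ventricular-like control preparations (**CT**) against
atrial-like, retinoic-acid-treated preparations (**AM**) before and after
compound addition, looking for chamber-specific electrophysiological effects
and arrhythmia-like events. `apscreen` implements that entire analysis chain
as a tested Python library with a thin CLI.

## What it computes

For every well, beats are detected and each optical action potential is
measured:

- **beat rate** (beats/min) and inter-beat intervals (IBI),
- **amplitude** above the local diastolic baseline,
- maximal **rising and falling slopes** of the fluorescence signal,
- **PWD_x** (pulse-width duration): the time from activation (maximum
  upstroke velocity) until the signal has decayed x% of the way back to
  baseline, for x ∈ {20, 30, 40, 50, 70, 80, 90},
- **Fridericia-corrected durations** PWD_xcF = PWD_x / IBI^(1/3) (IBI in s),
- **PWD30-80** = PWD80cF − PWD30cF and the **plateau width ratio**
  (PWD40−PWD30)/(PWD80−PWD70), which separates plateau-bearing ventricular
  morphology (ratio > 1) from spike-like atrial morphology (ratio < 1).

Parameters are averaged over a 30-s window per well. Post-compound wells are
additionally classified as **normal / irregular / EAD / arrest**
(early afterdepolarization = secondary maximum on the repolarization limb;
irregular = IBI coefficient of variation > 0.15; arrest = ≤ 1 beat per
window; priority arrest > EAD > irregular). Dose-response tables report the
per-well **percent change from the pre-compound baseline**,
100·(post − pre)/pre, as mean ± SD per (drug, group, concentration), with
Shapiro-Wilk-checked Student/Welch t comparisons and one-way ANOVA + Tukey
HSD for multi-group contrasts.

Because raw plate recordings from such screens are rarely public, the package
ships a **simulator** (`apscreen.simulate`) that generates traces with the
statistical structure the analysis assumes: calibrated CT/AM action-potential
shapes, Hill-type concentration-dependent parameter scaling, photobleaching
drift, Gaussian measurement noise, and injectable EAD / irregular / arrest
events with full ground truth. Every stage of the pipeline is verified
against that ground truth.

## Worked example

```python
import apscreen as ap

# one synthetic atrial-like well, 30 s at 5 ms sampling
trace, truth = ap.generate_trace(ap.AM_PRESET, duration=30.0,
                                 sampling_interval=5.0, seed=42)
detrended, beats, summary = ap.analyze_trace(trace)
print(f"wells beats: {summary.n_beats}   beat rate: {summary.beat_rate:.1f} /min")
print(f"PWD50  {summary.pwd[0.50]:.1f} ms   PWD50cF {summary.pwd_cf[0.50]:.1f} ms")
print(f"PWD90  {summary.pwd[0.90]:.1f} ms   PWD90cF {summary.pwd_cf[0.90]:.1f} ms")
call = ap.classify_well(detrended, beats, summary)
print(f"event label: {call.label}")
```

prints

```
wells beats: 118   beat rate: 237.3 /min
PWD50  72.4 ms   PWD50cF 114.5 ms
PWD90  99.1 ms   PWD90cF 156.7 ms
event label: normal
```

The atrial-like preset beats at ~237/min with corrected APD50/APD90 analogs
of ~115/156 ms — the fast, short-action-potential phenotype — and the
uncorrected durations are shorter than the corrected ones because the
cycle length is well below one second. The ventricular-like `CT_PRESET`
yields ~84 beats/min with corrected durations of ~160/316/370 ms at
20/50/90% decay.

From the shell, the same pipeline is:

```
apscreen simulate --config plate.yaml --out sim/
apscreen analyze  --traces sim/ --plate-map sim/plate_map.csv --out results/
apscreen report   --in results/ --out report/
```

producing `well_summary.csv`, `dose_response.csv`, `incidence.csv` and
`stats.csv` (column layouts documented in `apscreen/io.py`).

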