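"""Beat detection and action-potential waveform measurement.

This module turns a single-well fluorescence trace into the standard
evaluation parameters of plate-based membrane-potential screening:

* beat rate (beats/min) and inter-beat intervals,
* waveform amplitude above the local diastolic baseline,
* maximal rising and falling slopes of the optical signal,
* pulse-width durations PWD_x — the time from activation (maximum upstroke
  velocity) to x% repolarization ("decay"), for x in 20…90%,
* Fridericia rate-corrected durations (PWD_xcF = PWD_x / IBI^(1/3), IBI in s),
* PWD30-80 = PWD80 − PWD30 and the plateau width ratio
  (PWD40−PWD30)/(PWD80−PWD70),

averaged over a 30-s analysis window per well.

Measurement conventions (documented because the analytic unit tests rely on
them): activation is the first sample at/after the maximal first difference;
level crossings are located on a Savitzky-Golay-smoothed copy of the signal
(25-ms window, quadratic) with linear interpolation between samples and a
short persistence check so that noise dips do not trigger early crossings;
slopes are raw first differences divided by the sampling interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from ._errors import FormatError
from .io import Trace
from .presets import FRACTIONS

logger = logging.getLogger(__name__)

#: Smoothing window (ms) for level-crossing detection; time-based so results
#: are consistent across sampling intervals.
SMOOTH_MS = 25.0
#: Length (ms) of the pre-upstroke window whose median defines the local baseline.
BASELINE_MS = 50.0
#: Samples that must stay below a level for a crossing to be accepted.
CROSSING_PERSISTENCE = 5
#: Refractory floor (s) between detected beats.
MIN_LOCKOUT_S = 0.100


# ---------------------------------------------------------------------------
# Small numeric helpers (shared with the simulator's calibration loop)
# ---------------------------------------------------------------------------

def smooth_signal(y: np.ndarray, dt_ms: float, window_ms: float = SMOOTH_MS) -> np.ndarray:
    """Savitzky-Golay smoothing with a time-based window (quadratic)."""
    n = int(round(window_ms / dt_ms))
    if n % 2 == 0:
        n -= 1
    n = min(n, len(y) if len(y) % 2 == 1 else len(y) - 1)
    if n < 5:
        return np.asarray(y, float)
    return savgol_filter(np.asarray(y, float), n, 2)


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD estimated from the median absolute first difference.

    Beats are smooth relative to the sampling grid, so sample-to-sample
    differences are noise-dominated except on upstrokes, which the median
    ignores.
    """
    d = np.diff(np.asarray(y, float))
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def fridericia_correct(pwd_ms: float, ibi_s: float) -> float:
    """Fridericia cube-root rate correction: pwd / IBI^(1/3), IBI in seconds.

    The identity holds at IBI = 1 s.  Raises ``ValueError`` for IBI <= 0.
    """
    if ibi_s <= 0:
        raise ValueError(f"inter-beat interval must be positive, got {ibi_s}")
    return float(pwd_ms) / ibi_s ** (1.0 / 3.0)


#: Half-width (ms) of the local regression window used to refine crossings.
_CROSSING_FIT_MS = 12.0


def _downward_crossing(t: np.ndarray, ys: np.ndarray, start: int, stop: int,
                       level: float, persistence: int = CROSSING_PERSISTENCE) -> float | None:
    """First downward crossing of ``level`` in [start, stop), interpolated.

    Located on the smoothed signal; a candidate is accepted only if the
    median of the next ``persistence`` samples also sits at or below the
    level, which suppresses noise-induced early triggers.
    """
    seg = ys[start:stop]
    if seg.size < 2:
        return None
    below = seg <= level
    idx = np.flatnonzero(~below[:-1] & below[1:])
    for j in idx:
        tail = seg[j + 1: j + 1 + persistence]
        if np.median(tail) > level:
            continue
        y0, y1 = seg[j], seg[j + 1]
        frac = (y0 - level) / (y0 - y1) if y0 != y1 else 0.0
        return float(t[start + j] + frac * (t[start + j + 1] - t[start + j]))
    return None


def _measure_crossings(t: np.ndarray, y: np.ndarray, ys: np.ndarray, p: int,
                       hi: int, baseline: float, amplitude: float,
                       fractions: Sequence[float]) -> dict[float, float | None]:
    """Crossing times for every decay fraction with noise-debiased refinement.

    First-crossing times of a noisy signal are biased early, most strongly on
    slowly decaying plateaus.  Each candidate crossing is therefore refined
    by a linear regression of the *raw* signal over a window of up to ±12 ms,
    clipped to half the distance to the neighbouring level crossings so that
    closely spaced crossings on steep limbs (where the bias is negligible)
    stay independent.
    """
    dt = float(t[1] - t[0])
    cand: dict[float, tuple[float, float | None]] = {}
    for f in fractions:
        level = baseline + (1.0 - f) * amplitude
        cand[f] = (level, _downward_crossing(t, ys, p, hi, level))
    times = sorted(tc for _, tc in cand.values() if tc is not None)
    out: dict[float, float | None] = {}
    wmax = _CROSSING_FIT_MS / 1000.0
    for f in fractions:
        level, tc = cand[f]
        if tc is None:
            out[f] = None
            continue
        k = times.index(tc)
        left = tc - (times[k - 1] + tc) / 2 if k > 0 else wmax
        right = (times[k + 1] + tc) / 2 - tc if k + 1 < len(times) else wmax
        # symmetric window (an asymmetric fit leans into curvature on the
        # longer side); iterate with re-centering so a noise-shifted first
        # crossing does not anchor the fit off the true crossing
        w = min(left, right, wmax)
        tc0 = tc
        for _ in range(3):
            tc_fit = _line_fit_crossing(t, y, tc, level, w, p, hi, dt)
            if tc_fit is None or not (tc0 - 3 * w <= tc_fit <= tc0 + 3 * w):
                break
            if abs(tc_fit - tc) < 0.1 * dt:
                tc = float(tc_fit)
                break
            tc = float(tc_fit)
        out[f] = tc
    return out


def _line_fit_crossing(t, y, center, level, w, p, hi, dt) -> float | None:
    """Crossing of ``level`` from a raw-signal line fit over ``center`` ± ``w``."""
    i0 = max(int(np.ceil((center - w - t[0]) / dt)), p)
    i1 = min(int(np.floor((center + w - t[0]) / dt)) + 1, hi)
    if i1 - i0 < 3:
        return None
    tt, yy = t[i0:i1], y[i0:i1]
    slope, intercept = np.polyfit(tt - center, yy, 1)
    if slope >= 0:
        return None
    return float(center + (level - intercept) / slope)


# ---------------------------------------------------------------------------
# Beat container
# ---------------------------------------------------------------------------

@dataclass
class Beat:
    """One detected and measured action-potential waveform."""

    peak_index: int
    t_activation: float              # s, time of maximum upstroke velocity
    t_peak: float                    # s
    amplitude: float                 # fluorescence units above local baseline
    baseline: float
    v_up_max: float                  # units/s, rising slope
    v_down_max: float                # units/s, falling slope (positive)
    pwd: dict[float, float | None] = field(default_factory=dict)  # fraction -> ms
    ibi_prev: float | None = None    # s, from previous activation

    def pwd_corrected(self, fraction: float) -> float | None:
        v = self.pwd.get(fraction)
        if v is None or self.ibi_prev is None:
            return None
        return fridericia_correct(v, self.ibi_prev)


def plateau_ratio(pwd: Mapping[float, float | None] | Beat) -> float | None:
    """Plateau width ratio (PWD40 − PWD30) / (PWD80 − PWD70).

    > 1 for plateau-bearing (ventricular-like) morphologies, < 1 for
    spike-like (atrial-like) ones.  Returns ``None`` if any constituent is
    undefined.  The ratio is invariant under rate correction.
    """
    if isinstance(pwd, Beat):
        pwd = pwd.pwd
    vals = [pwd.get(f) for f in (0.30, 0.40, 0.70, 0.80)]
    if any(v is None for v in vals):
        return None
    p30, p40, p70, p80 = vals
    denom = p80 - p70
    if denom <= 0:
        return None
    return (p40 - p30) / denom


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------

def detrend(trace: Trace) -> Trace:
    """Remove slow baseline drift (photobleaching) from a trace.

    A rolling 10th-percentile baseline over a window of 3x the median beat
    period (fallback 2 s when no beats are found) is subtracted.  Traces
    shorter than one baseline window pass through unchanged with a warning.
    """
    y = trace.signal
    dt = trace.dt_s
    ys = smooth_signal(y, trace.sampling_interval)
    sigma = robust_noise_sd(y)
    prominence = max(5.0 * sigma, 1e-12)
    peaks, _ = find_peaks(ys, prominence=prominence, distance=max(int(MIN_LOCKOUT_S / dt), 1))
    if len(peaks) >= 3:
        period = float(np.median(np.diff(peaks))) * dt
    else:
        period = 2.0 / 3.0  # fallback -> 2 s window
    window_s = 3.0 * period
    n_win = int(round(window_s / dt))
    if n_win % 2 == 0:
        n_win += 1
    if n_win >= len(y):
        logger.warning(
            "trace %s shorter than one baseline window (%.1f s); detrend is a pass-through",
            trace.well_id, window_s,
        )
        return trace.copy_with(y.copy())
    baseline = (
        pd.Series(y).rolling(n_win, center=True, min_periods=1).quantile(0.10).to_numpy()
    )
    return trace.copy_with(y - baseline)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_beats(trace: Trace) -> list[Beat]:
    """Detect and measure the beats of a (detrended) trace.

    Two-pass peak detection: a first pass with a prominence floor of 5x the
    robust noise SD bootstraps the running beat amplitude and inter-beat
    interval; the second pass uses a prominence of 30% of the median beat
    amplitude and a refractory lockout of 50% of the median IBI (floor
    100 ms).  Candidate sets whose median prominence is indistinguishable
    from the noise tail (< 10x noise SD) are rejected, so a flat noisy trace
    yields an empty list — the downstream signature of arrest.  Beats clipped
    by the trace edges are discarded.
    """
    y = trace.signal
    dt = trace.dt_s
    ys = smooth_signal(y, trace.sampling_interval)
    sigma = robust_noise_sd(y)
    floor = max(5.0 * sigma, 1e-12)
    lockout = max(int(MIN_LOCKOUT_S / dt), 1)

    peaks, props = find_peaks(ys, prominence=floor, distance=lockout)
    if len(peaks) == 0:
        return []
    med_amp = float(np.median(props["prominences"]))
    if sigma > 0 and med_amp < 10.0 * sigma:
        return []  # candidates indistinguishable from noise: no beats
    if len(peaks) >= 2:
        med_ibi = float(np.median(np.diff(peaks))) * dt
    else:
        med_ibi = trace.duration_s
    distance = max(int(max(0.5 * med_ibi, MIN_LOCKOUT_S) / dt), 1)
    peaks, props = find_peaks(ys, prominence=0.30 * med_amp, distance=distance)
    if len(peaks) == 0:
        return []

    bounds = np.concatenate([[0], peaks, [len(y)]])
    beats: list[Beat] = []
    back = max(int(0.5 * med_ibi / dt), 2)
    for j, p in enumerate(peaks):
        lo = int(bounds[j])
        hi = int(bounds[j + 2]) if j + 2 < len(bounds) else len(y)
        hi = min(hi, len(y))
        b = _measure_single(trace.time, y, ys, peak_hint=int(p), lo=lo, hi=hi,
                            back=back, dt=dt)
        if b is not None:
            beats.append(b)

    # refine boundaries: limit each beat's crossing search at the next activation
    beats = _remeasure_with_activations(trace, beats)
    prev = None
    for b in beats:
        b.ibi_prev = (b.t_activation - prev) if prev is not None else None
        prev = b.t_activation
    return beats


def _refine_activation(t: np.ndarray, dy: np.ndarray, dys: np.ndarray, a: int,
                       dt: float, s_lo: int | None = None,
                       s_hi: int | None = None) -> float:
    """Sub-sample activation time around the first-difference maximum at ``a``.

    For a resolved (smooth) upstroke the maximum of the *time-smoothed*
    derivative is located and refined with a three-point parabola, which
    recovers the same continuous max-slope time on any sampling grid even
    when the velocity peak is skewed.  An upstroke that is unresolved at the
    sampling interval (raw neighbouring differences < 20% of the maximum,
    e.g. an idealized instantaneous step) is assigned the first sample at or
    after the jump instead.
    """
    dm = dy[a - 1] if a - 1 >= 0 else 0.0
    dp = dy[a + 1] if a + 1 < len(dy) else 0.0
    if dy[a] <= 0 or (dm < 0.2 * dy[a] and dp < 0.2 * dy[a]):
        return float(t[a + 1])
    half = max(int(round(SMOOTH_MS / 1000.0 / dt / 2)), 2)
    lo = max(a - half, 0 if s_lo is None else s_lo, 0)
    hi = min(a + half + 1, len(dys) if s_hi is None else s_hi, len(dys))
    if hi <= lo:
        return float(t[a + 1])
    m = lo + int(np.argmax(dys[lo:hi]))
    # midpoint of the half-maximum crossings of the smoothed derivative: for
    # a noisy, skewed velocity peak this is far more stable than the argmax,
    # and its fixed shape-dependent offset cancels through calibration
    level = 0.5 * dys[m]
    r = m
    while r > lo and dys[r - 1] > level:
        r -= 1
    f = m
    stop = min(s_hi if s_hi is not None else len(dys), len(dys))
    while f < stop - 1 and dys[f + 1] > level:
        f += 1
    if r > lo and dys[r - 1] != dys[r]:
        tr_ = (r - 1) + (level - dys[r - 1]) / (dys[r] - dys[r - 1])
    else:
        tr_ = float(r)
    if f < stop - 1 and dys[f] != dys[f + 1]:
        tf_ = f + (dys[f] - level) / (dys[f] - dys[f + 1])
    else:
        tf_ = float(f)
    mid = 0.5 * (tr_ + tf_)
    return float(t[0] + dt * (mid + 0.5))


#: Half-width (s) of the derivative search window around the upstroke.
_UPSTROKE_WIN_S = 0.060


def _measure_single(t, y, ys, peak_hint, lo, hi, back, dt,
                    fractions: Sequence[float] = FRACTIONS) -> Beat | None:
    dy = np.diff(y)
    a_lo = max(lo, peak_hint - back)
    if peak_hint <= a_lo:
        return None
    # localize the upstroke by the (noise-robust) half-amplitude upward
    # crossing of the smoothed signal, then search the derivatives only in a
    # narrow window around it — a wide search latches onto noise spikes
    diastole = float(np.percentile(ys[a_lo:peak_hint + 1], 10))
    half_level = diastole + 0.5 * (ys[peak_hint] - diastole)
    below = np.flatnonzero(ys[a_lo:peak_hint] < half_level)
    ihalf = a_lo + (int(below[-1]) + 1 if below.size else 0)
    w = max(int(round(_UPSTROKE_WIN_S / dt)), 2)
    s_lo = max(ihalf - w, a_lo)
    s_hi = min(ihalf + w, peak_hint)
    if s_hi <= s_lo:
        return None
    a = s_lo + int(np.argmax(dy[s_lo:s_hi]))
    v_up = dy[a] / dt
    t_act = _refine_activation(t, dy, np.diff(ys), a, dt, s_lo, s_hi)
    # walk back to the upstroke foot: first difference falls below 5% of max
    thr = 0.05 * dy[a]
    k = a
    while k > lo and dy[k - 1] > thr:
        k -= 1
    foot = k
    nb = int(round(BASELINE_MS / 1000.0 / dt))
    b_lo = max(foot - nb, 0)
    if foot - b_lo < 3:
        return None  # clipped at the left edge: no baseline window
    baseline = float(np.median(y[b_lo:foot]))

    # refine the detected peak on the raw signal, but only locally: a global
    # argmax up to the next beat could land on that beat's rising edge
    k = max(int(round(0.020 / dt)), 2)
    p_lo = max(a + 1, peak_hint - k)
    p_hi = min(hi, peak_hint + k + 1)
    if p_hi <= p_lo:
        p_lo, p_hi = a + 1, min(hi, a + 2)
    p = p_lo + int(np.argmax(y[p_lo:p_hi]))
    amplitude = float(y[p] - baseline)
    if amplitude <= 0:
        return None
    crossings = _measure_crossings(t, y, ys, p, hi, baseline, amplitude, fractions)
    pwd: dict[float, float | None] = {
        f: (None if tc is None else (tc - t_act) * 1000.0)
        for f, tc in crossings.items()
    }
    if hi >= len(y) and pwd.get(max(fractions)) is None:
        return None  # clipped at the right edge before full repolarization
    v_down = -float(np.min(dy[p:hi - 1])) / dt if hi - 1 > p else np.nan
    return Beat(
        peak_index=p, t_activation=t_act, t_peak=float(t[p]), amplitude=amplitude,
        baseline=baseline, v_up_max=float(v_up), v_down_max=v_down, pwd=pwd,
    )


def _remeasure_with_activations(trace: Trace, beats: list[Beat]) -> list[Beat]:
    """Final crossing measurement with ensemble-informed fit windows.

    First-crossing candidates are collected per beat (bounded by the next
    activation).  The per-well *median* crossing offset then places each
    beat's regression window: because the window placement no longer depends on the
    beat's own noise realization, the per-beat line-fit crossing estimate is
    unbiased even on segments sampled by only a few points.
    """
    if not beats:
        return beats
    y = trace.signal
    ys = smooth_signal(y, trace.sampling_interval)
    t = trace.time
    dt = trace.dt_s
    acts = [int(round((b.t_activation - t[0]) / dt)) for b in beats]
    fractions = list(beats[0].pwd)

    cand: list[dict[float, float | None]] = []
    for j, b in enumerate(beats):
        hi = acts[j + 1] if j + 1 < len(beats) else len(y)
        offsets = {}
        for f in fractions:
            level = b.baseline + (1.0 - f) * b.amplitude
            tc = _downward_crossing(t, ys, b.peak_index, hi, level)
            offsets[f] = None if tc is None else tc - b.t_activation
        cand.append(offsets)

    med: dict[float, float | None] = {}
    for f in fractions:
        vals = [c[f] for c in cand if c[f] is not None]
        med[f] = float(np.median(vals)) if vals else None
    offs = sorted(v for v in med.values() if v is not None)
    wmax = _CROSSING_FIT_MS / 1000.0
    win: dict[float, float] = {}
    for f in fractions:
        m = med[f]
        if m is None:
            continue
        k = offs.index(m)
        left = m - (offs[k - 1] + m) / 2 if k > 0 else wmax
        right = (offs[k + 1] + m) / 2 - m if k + 1 < len(offs) else wmax
        win[f] = min(left, right, wmax)

    for j, b in enumerate(beats):
        hi = acts[j + 1] if j + 1 < len(beats) else len(y)
        for f in fractions:
            tc0 = cand[j][f]
            if tc0 is None:
                b.pwd[f] = None
                continue
            tc = b.t_activation + tc0
            m = med[f]
            if m is not None:
                center = b.t_activation + m
                fit = _line_fit_crossing(t, y, center, b.baseline + (1.0 - f) * b.amplitude,
                                         win[f], b.peak_index, hi, dt)
                if fit is not None and abs(fit - center) <= 3 * win[f]:
                    tc = fit
            b.pwd[f] = (tc - b.t_activation) * 1000.0
    return beats


def measure_waveform(t: np.ndarray, y: np.ndarray,
                     fractions: Sequence[float] = FRACTIONS) -> Beat | None:
    """Measure a single clean beat given on its own time axis.

    Used by the simulator's calibration loop and for ground-truth slope
    bookkeeping, with the same conventions as :func:`detect_beats`.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    dt = float(t[1] - t[0])
    ys = smooth_signal(y, dt * 1000.0)
    p = int(np.argmax(ys))
    return _measure_single(t, y, ys, peak_hint=p, lo=0, hi=len(y), back=p, dt=dt,
                           fractions=fractions)


# ---------------------------------------------------------------------------
# Well summary
# ---------------------------------------------------------------------------

@dataclass
class WellSummary:
    """30-s-window averages of all evaluation parameters for one well."""

    well_id: str
    n_beats: int
    window: tuple[float, float]
    beat_rate: float = np.nan        # beats/min
    amplitude_mean: float = np.nan
    v_up_mean: float = np.nan
    v_down_mean: float = np.nan
    v_up_norm_mean: float = np.nan   # 1/s, velocity / amplitude
    v_down_norm_mean: float = np.nan
    pwd: dict[float, float] = field(default_factory=dict)       # ms, uncorrected
    pwd_cf: dict[float, float] = field(default_factory=dict)    # ms, Fridericia-corrected
    pwd30_80: float = np.nan         # ms, corrected PWD80cF - PWD30cF
    pwd30_80_uncorrected: float = np.nan
    plateau_ratio: float = np.nan
    ibi_cv: float = np.nan
    n_undefined_pwd: int = 0

    def to_row(self) -> dict:
        row = {
            "well": self.well_id, "n_beats": self.n_beats,
            "beat_rate": self.beat_rate, "amplitude_mean": self.amplitude_mean,
            "v_up_mean": self.v_up_mean, "v_down_mean": self.v_down_mean,
            "v_up_norm_mean": self.v_up_norm_mean, "v_down_norm_mean": self.v_down_norm_mean,
            "pwd30_80": self.pwd30_80, "pwd30_80_uncorrected": self.pwd30_80_uncorrected,
            "plateau_ratio": self.plateau_ratio, "ibi_cv": self.ibi_cv,
            "window_start_s": self.window[0], "window_end_s": self.window[1],
        }
        for f in FRACTIONS:
            row[f"pwd{int(round(f * 100))}"] = self.pwd.get(f, np.nan)
            row[f"pwd{int(round(f * 100))}cF"] = self.pwd_cf.get(f, np.nan)
        return row


def _nanmean(values: Iterable[float | None]) -> float:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def summarize_well(beats: Sequence[Beat], window: tuple[float, float] = (0.0, 30.0),
                   well_id: str = "") -> WellSummary:
    """Average the evaluation parameters over beats activated inside ``window``.

    The beat rate is (n−1)/(t_last−t_first)·60 for n ≥ 2; the Fridericia
    correction is applied per beat with its own preceding IBI and then
    averaged.  Beats with undefined PWDs are excluded from the affected means
    but still counted for rate.  n = 0 yields an all-NaN summary (the arrest
    candidate downstream).
    """
    w0, w1 = window
    sel = [b for b in beats if w0 <= b.t_activation <= w1]
    out = WellSummary(well_id=well_id, n_beats=len(sel), window=(w0, w1))
    if not sel:
        return out
    if len(sel) >= 2:
        span = sel[-1].t_activation - sel[0].t_activation
        if span > 0:
            out.beat_rate = (len(sel) - 1) / span * 60.0
    out.amplitude_mean = _nanmean(b.amplitude for b in sel)
    out.v_up_mean = _nanmean(b.v_up_max for b in sel)
    out.v_down_mean = _nanmean(b.v_down_max for b in sel)
    out.v_up_norm_mean = _nanmean(
        b.v_up_max / b.amplitude for b in sel if b.amplitude > 0)
    out.v_down_norm_mean = _nanmean(
        b.v_down_max / b.amplitude for b in sel if b.amplitude > 0)
    for f in FRACTIONS:
        out.pwd[f] = _nanmean(b.pwd.get(f) for b in sel)
        out.pwd_cf[f] = _nanmean(b.pwd_corrected(f) for b in sel)
    diffs_cf, diffs_unc = [], []
    for b in sel:
        p30, p80 = b.pwd.get(0.30), b.pwd.get(0.80)
        if p30 is not None and p80 is not None:
            diffs_unc.append(p80 - p30)
            if b.ibi_prev is not None:
                diffs_cf.append(fridericia_correct(p80, b.ibi_prev)
                                - fridericia_correct(p30, b.ibi_prev))
    out.pwd30_80 = float(np.mean(diffs_cf)) if diffs_cf else np.nan
    out.pwd30_80_uncorrected = float(np.mean(diffs_unc)) if diffs_unc else np.nan
    out.plateau_ratio = _nanmean(plateau_ratio(b) for b in sel)
    ibis = np.array([b.ibi_prev for b in sel if b.ibi_prev is not None], float)
    if ibis.size >= 2 and ibis.mean() > 0:
        out.ibi_cv = float(ibis.std(ddof=1) / ibis.mean())
    elif ibis.size >= 1:
        out.ibi_cv = 0.0
    out.n_undefined_pwd = sum(
        1 for b in sel for f in FRACTIONS if b.pwd.get(f) is None)
    if out.n_undefined_pwd:
        logger.debug("well %s: %d undefined PWD values excluded from averaging",
                     well_id, out.n_undefined_pwd)
    return out


def analyze_trace(trace: Trace, window_s: float = 30.0) -> tuple[Trace, list[Beat], WellSummary]:
    """Convenience: detrend, detect, measure and summarize one trace."""
    det = detrend(trace)
    beats = detect_beats(det)
    t0 = float(trace.time[0])
    summary = summarize_well(beats, window=(t0, t0 + window_s), well_id=trace.well_id)
    return det, beats, summary
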