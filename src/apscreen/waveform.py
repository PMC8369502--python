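"""Single-beat waveform construction and preset calibration.

The simulator's beat is a logistic upstroke multiplied by a repolarization
profile built from a weighted sum of three exponential decays plus an
optional plateau sigmoid — enough degrees of freedom to realize both
plateau-bearing (ventricular-like) and spike-like (atrial-like)
morphologies.

Calibration makes the *measured* durations of the noise-free beat hit the
preset's APD targets: a bounded least-squares fit of the shape parameters is
followed by a monotone (PCHIP) time-warp refinement of the repolarization
limb, which pins every targeted level crossing to well under a millisecond.
The calibration loop measures candidate waveforms with exactly the same
routine the analysis pipeline uses (:func:`apscreen.beats.measure_waveform`),
so generator and analyzer agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from ._errors import CalibrationError
from .beats import measure_waveform
from .presets import PhenotypePreset

#: Internal template grid (ms); fine enough that interpolation onto any
#: supported acquisition grid (5 or 10 ms typical) is sub-sample accurate.
TEMPLATE_DT_MS = 0.5

_MAX_WARP_ITER = 60
_WARP_DAMPING = 0.5   # fraction of the measured error corrected per iteration
_FIT_MAX_NFEV = 400


@dataclass(frozen=True)
class BeatTemplate:
    """A calibrated, noise-free single-beat waveform (peak normalized to 1)."""

    t: np.ndarray        # s, from template start; uniform TEMPLATE_DT_MS grid
    y: np.ndarray        # normalized fluorescence, 0 at baseline, 1 at peak
    t_act: float         # s, activation (max upstroke velocity) within the template
    v_up: float          # 1/s, max rising slope of the normalized template
    v_down: float        # 1/s, max falling slope (positive)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1])

    @property
    def post_activation_s(self) -> float:
        return float(self.t[-1] - self.t_act)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of :func:`calibrate_preset`."""

    preset: PhenotypePreset
    template: BeatTemplate
    params: tuple[float, ...]          # fitted shape parameters (pre-warp)
    residuals_ms: tuple[tuple[float, float], ...]  # (fraction, measured - target)
    uncorrected_targets: tuple[tuple[float, float], ...]

    def residual(self, fraction: float) -> float:
        return dict(self.residuals_ms)[fraction]

    @property
    def max_abs_residual_ms(self) -> float:
        return max(abs(r) for _, r in self.residuals_ms)


def _build_waveform(theta: np.ndarray, t_ms: np.ndarray, t0_ms: float,
                    tau_up_ms: float) -> np.ndarray:
    """Logistic upstroke x (3-term exponential decay + plateau sigmoid)."""
    w1, w2, w3, tau1, tau2, tau3, wp, tp, sp = theta
    up = 1.0 / (1.0 + np.exp(-(t_ms - t0_ms) / tau_up_ms))
    s = np.maximum(t_ms - t0_ms, 0.0)
    decay = (w1 * np.exp(-s / tau1) + w2 * np.exp(-s / tau2) + w3 * np.exp(-s / tau3)
             + wp / (1.0 + np.exp((s - tp) / sp)))
    y = up * np.maximum(decay, 0.0)
    m = y.max()
    return y / m if m > 0 else y


def _measure_ms(t_s: np.ndarray, y: np.ndarray, fractions) -> dict[float, float | None]:
    beat = measure_waveform(t_s, y, fractions=fractions)
    if beat is None:
        return {f: None for f in fractions}
    return dict(beat.pwd)


def _fit_shape(preset: PhenotypePreset, t_ms: np.ndarray, t0_ms: float) -> np.ndarray:
    targets = preset.targets()
    fracs = list(targets)
    goal = np.array([targets[f] for f in fracs])
    apd90 = goal[-1]
    apd50 = preset.apd(0.50)
    support_ms = float(t_ms[-1])
    t_s = t_ms / 1000.0
    tau_up = preset.upstroke_time_constant

    def residual(theta):
        y = _build_waveform(theta, t_ms, t0_ms, tau_up)
        pwd = _measure_ms(t_s, y, fracs)
        return np.array([
            (pwd[f] - targets[f]) if pwd[f] is not None else support_ms
            for f in fracs
        ])

    lo = [0.0] * 3 + [3.0] * 3 + [0.0, 0.0, 2.0]
    hi = [5.0] * 3 + [4.0 * apd90] * 3 + [5.0, 1.3 * apd90, apd90]
    sp0 = max((apd90 - apd50) / 3.0, 5.0)
    inits = [
        np.array([0.4, 0.4, 0.2, max(apd50 / 2, 4), apd90 * 0.8, apd90 * 2.0,
                  0.3, apd50, sp0]),
        np.array([0.2, 0.2, 0.1, max(apd50 / 2, 4), apd90 * 0.8, apd90 * 2.0,
                  1.2, apd50, max(sp0 / 2, 3.0)]),
    ]
    best, best_cost = None, np.inf
    for x0 in inits:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), max_nfev=_FIT_MAX_NFEV,
                                diff_step=1e-3)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    if best is None:
        raise CalibrationError(
            f"shape fit failed for preset {preset.name!r}", residuals_ms=dict.fromkeys(targets, np.inf)
        )
    return best


def _warp_once(t_s: np.ndarray, y: np.ndarray, targets_ms: dict[float, float]
               ) -> tuple[np.ndarray, dict[float, float | None]]:
    """One monotone time-warp of the repolarization limb toward the targets."""
    fracs = list(targets_ms)
    pwd = _measure_ms(t_s, y, fracs)
    if any(pwd[f] is None for f in fracs):
        return y, pwd
    beat = measure_waveform(t_s, y, fractions=fracs)
    t_act = beat.t_activation
    # damped correction: aim only part of the way toward the target so that
    # smoothing-induced coupling between nearby crossings cannot oscillate
    aim = {f: pwd[f] + _WARP_DAMPING * (targets_ms[f] - pwd[f]) for f in fracs}
    knots_new = np.array([t_act] + [t_act + aim[f] / 1000.0 for f in fracs])
    knots_old = np.array([t_act] + [t_act + pwd[f] / 1000.0 for f in fracs])
    if np.any(np.diff(knots_new) <= 0) or np.any(np.diff(knots_old) <= 0):
        return y, pwd
    interp = PchipInterpolator(knots_new, knots_old)
    w = np.array(t_s, float)
    inside = (t_s > t_act) & (t_s <= knots_new[-1])
    w[inside] = interp(t_s[inside])
    beyond = t_s > knots_new[-1]
    end_slope = ((knots_old[-1] - knots_old[-2]) / (knots_new[-1] - knots_new[-2]))
    w[beyond] = knots_old[-1] + end_slope * (t_s[beyond] - knots_new[-1])
    w = np.clip(w, t_s[0], t_s[-1])
    y_new = np.array(y, float)
    region = t_s > t_act
    y_new[region] = np.interp(w[region], t_s, y)
    return y_new, pwd


def calibrate_preset(preset: PhenotypePreset, tolerance_ms: float = 1.0) -> CalibrationResult:
    """Calibrate the single-beat template of ``preset``.

    Returns a :class:`CalibrationResult` whose noise-free template, when
    measured by the analysis pipeline's own routine, reproduces every APD
    target to within ``tolerance_ms`` (typically well under 0.1 ms).  Raises
    :class:`CalibrationError` with the residuals if the fit plus warp
    refinement cannot reach the tolerance.
    """
    targets = preset.targets()
    fracs = list(targets)
    apd90 = targets[max(fracs)]
    tau_up = preset.upstroke_time_constant
    t0_ms = max(5.0 * tau_up, 60.0)
    ibi_ms = preset.ibi_s * 1000.0
    # cap the tail near one inter-beat interval, but never squeeze the support
    # below the slowest targeted crossing (overlapping tails are summed when
    # beats are rendered, so a modest overshoot is harmless)
    support_ms = min(t0_ms + 1.35 * apd90 + 80.0,
                     max(0.92 * ibi_ms, t0_ms + apd90 + 50.0))
    t_ms = np.arange(0.0, support_ms + TEMPLATE_DT_MS, TEMPLATE_DT_MS)
    t_s = t_ms / 1000.0

    theta = _fit_shape(preset, t_ms, t0_ms)
    y = _build_waveform(theta, t_ms, t0_ms, tau_up)

    def max_resid(p):
        return max(abs(p[f] - targets[f]) if p[f] is not None else np.inf for f in fracs)

    pwd = _measure_ms(t_s, y, fracs)
    best_y, best_pwd = y, pwd
    for _ in range(_MAX_WARP_ITER):
        if max_resid(pwd) < 0.05:
            break
        y, _ = _warp_once(t_s, y, targets)
        pwd = _measure_ms(t_s, y, fracs)
        if max_resid(pwd) < max_resid(best_pwd):
            best_y, best_pwd = y, pwd
    y, pwd = best_y, best_pwd

    residuals = {
        f: (pwd[f] - targets[f]) if pwd[f] is not None else np.inf for f in fracs
    }
    if max(abs(r) for r in residuals.values()) > tolerance_ms:
        raise CalibrationError(
            f"calibration of preset {preset.name!r} did not reach {tolerance_ms} ms "
            f"(residuals: { {f: round(r, 3) for f, r in residuals.items()} })",
            residuals_ms=residuals,
        )

    # taper the tail smoothly to zero so rendered beats end at baseline
    m = y.max()
    y = y / m
    taper_ms = 40.0
    n_taper = int(taper_ms / TEMPLATE_DT_MS)
    ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_taper)))
    y[-n_taper:] *= ramp
    y[-1] = 0.0

    beat = measure_waveform(t_s, y, fractions=fracs)
    template = BeatTemplate(
        t=t_s, y=y, t_act=beat.t_activation,
        v_up=beat.v_up_max, v_down=beat.v_down_max,
    )
    return CalibrationResult(
        preset=preset, template=template, params=tuple(theta),
        residuals_ms=tuple(sorted(residuals.items())),
        uncorrected_targets=tuple(sorted(targets.items())),
    )


@lru_cache(maxsize=32)
def calibrated(preset: PhenotypePreset) -> CalibrationResult:
    """Cached calibration (presets are frozen, hence hashable)."""
    return calibrate_preset(preset)
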