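"""Cardiomyocyte phenotype presets and phenomenological drug-effect models.

A :class:`PhenotypePreset` captures everything the simulator needs to draw a
well's spontaneous optical action potentials: beating rate, the repolarization
time targets (APD_x at the canonical decay fractions), upstroke kinetics,
signal scale, measurement noise, photobleaching drift, and beat-to-beat rate
jitter.

Two default presets are provided, modelled on the two preparations of a
voltage-dye plate assay of hiPSC-derived cardiomyocytes:

``CT``
    control (ventricular-like) cells — slow rate, long plateau-bearing action
    potential (APD30–40/APD70–80 width ratio > 1).
``AM``
    retinoic-acid-treated (atrial-like) cells — fast rate, short spike-like
    action potential (width ratio < 1).

Published duration values for such preparations are rate-corrected (cAPD,
Fridericia).  Presets therefore accept *corrected* targets and store the
*uncorrected* generation targets obtained by inverting the Fridericia formula
at the preset's own rate, so that a rate-correcting analysis pipeline lands
back on the corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._errors import InvalidConfigError

#: Repolarization (decay) fractions at which durations are defined.
FRACTIONS: tuple[float, ...] = (0.20, 0.30, 0.40, 0.50, 0.70, 0.80, 0.90)

#: Parameters a drug effect may target.
EFFECT_TARGETS = ("beat_rate", "upstroke_velocity_scale", "decay_velocity_scale", "apd_scale")


def fridericia_invert(capd_ms: float, ibi_s: float) -> float:
    """Uncorrected duration whose Fridericia correction at ``ibi_s`` is ``capd_ms``."""
    if ibi_s <= 0:
        raise ValueError(f"inter-beat interval must be positive, got {ibi_s}")
    return capd_ms * ibi_s ** (1.0 / 3.0)


def _as_target_items(targets: Mapping[float, float]) -> tuple[tuple[float, float], ...]:
    items = tuple(sorted((float(f), float(v)) for f, v in targets.items()))
    return items


@dataclass(frozen=True)
class PhenotypePreset:
    """Simulator parameterization of one cardiomyocyte subtype.

    ``apd_targets`` holds *uncorrected* durations (ms) keyed by decay
    fraction; use :meth:`from_corrected` to build a preset from
    rate-corrected (cAPD) values.
    """

    name: str
    beat_rate: float                      # beats/min
    apd_targets: tuple[tuple[float, float], ...]  # (fraction, uncorrected ms)
    amplitude: float = 1.0                # arbitrary fluorescence units
    upstroke_time_constant: float = 8.0   # ms, logistic time constant
    baseline_level: float = 10.0          # arbitrary fluorescence units
    noise_sd: float = 0.01                # fraction of amplitude
    drift_rate: float = 0.03              # fraction of amplitude per minute
    rate_jitter_cv: float = 0.02          # CV of inter-beat intervals

    def __post_init__(self):
        object.__setattr__(self, "apd_targets", _as_target_items(dict(self.apd_targets)))
        if self.beat_rate <= 0:
            raise InvalidConfigError(f"beat_rate must be positive, got {self.beat_rate}")
        if self.amplitude <= 0:
            raise InvalidConfigError(f"amplitude must be positive, got {self.amplitude}")
        if self.noise_sd < 0:
            raise InvalidConfigError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.upstroke_time_constant <= 0:
            raise InvalidConfigError("upstroke_time_constant must be positive")
        if self.rate_jitter_cv < 0:
            raise InvalidConfigError("rate_jitter_cv must be non-negative")
        fracs = [f for f, _ in self.apd_targets]
        vals = [v for _, v in self.apd_targets]
        if len(fracs) < 2:
            raise InvalidConfigError("at least two APD targets are required")
        if any(not 0 < f < 1 for f in fracs):
            raise InvalidConfigError("decay fractions must lie in (0, 1)")
        if any(b - a <= 0 for a, b in zip(vals, vals[1:])):
            raise InvalidConfigError(
                f"apd_targets must be strictly increasing in fraction, got {vals}"
            )
        if vals[-1] >= 60000.0 / self.beat_rate:
            raise InvalidConfigError(
                f"APD{int(round(fracs[-1] * 100))} = {vals[-1]:.1f} ms does not fit in the "
                f"{60000.0 / self.beat_rate:.1f} ms inter-beat interval at {self.beat_rate}/min"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def ibi_s(self) -> float:
        """Mean inter-beat interval in seconds."""
        return 60.0 / self.beat_rate

    @property
    def fridericia_factor(self) -> float:
        """Cube root of the mean IBI (s); divide by it to rate-correct."""
        return self.ibi_s ** (1.0 / 3.0)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(f for f, _ in self.apd_targets)

    def apd(self, fraction: float) -> float:
        """Uncorrected target duration (ms) at ``fraction``, interpolating if needed."""
        fracs = np.array([f for f, _ in self.apd_targets])
        vals = np.array([v for _, v in self.apd_targets])
        if not fracs[0] <= fraction <= fracs[-1]:
            raise ValueError(f"fraction {fraction} outside target range [{fracs[0]}, {fracs[-1]}]")
        return float(np.interp(fraction, fracs, vals))

    def targets(self) -> dict[float, float]:
        """Uncorrected targets as a plain dict {fraction: ms}."""
        return dict(self.apd_targets)

    def corrected_targets(self) -> dict[float, float]:
        """Fridericia-corrected targets {fraction: ms} at the preset rate."""
        return {f: v / self.fridericia_factor for f, v in self.apd_targets}

    @classmethod
    def from_corrected(cls, name: str, beat_rate: float,
                       capd_targets: Mapping[float, float], **kwargs) -> "PhenotypePreset":
        """Build a preset from rate-corrected durations by Fridericia inversion."""
        ibi = 60.0 / beat_rate
        targets = {f: fridericia_invert(v, ibi) for f, v in capd_targets.items()}
        return cls(name=name, beat_rate=beat_rate, apd_targets=_as_target_items(targets), **kwargs)

    def with_targets(self, targets: Mapping[float, float]) -> "PhenotypePreset":
        return replace(self, apd_targets=_as_target_items(targets))


# ---------------------------------------------------------------------------
# Default presets.  cAPD20/50/90 anchors are the published plate-assay values
# for the two preparations; the intermediate fractions are calibration choices
# that realize the published APD30-40/APD70-80 width ratios (CT 1.30, AM 0.75)
# while keeping the set monotone.  See docs/methods.md.
# ---------------------------------------------------------------------------

CT_CAPD_TARGETS: dict[float, float] = {
    0.20: 159.8, 0.30: 221.8, 0.40: 254.3, 0.50: 315.5,
    0.70: 332.5, 0.80: 357.5, 0.90: 369.7,
}

AM_CAPD_TARGETS: dict[float, float] = {
    0.20: 69.8, 0.30: 84.8, 0.40: 96.8, 0.50: 114.9,
    0.70: 129.9, 0.80: 145.9, 0.90: 156.1,
}

CT_PRESET = PhenotypePreset.from_corrected(
    "CT", beat_rate=83.7, capd_targets=CT_CAPD_TARGETS, upstroke_time_constant=8.0
)

AM_PRESET = PhenotypePreset.from_corrected(
    "AM", beat_rate=237.0, capd_targets=AM_CAPD_TARGETS, upstroke_time_constant=3.0
)

DEFAULT_PRESETS: dict[str, PhenotypePreset] = {"CT": CT_PRESET, "AM": AM_PRESET}


# ---------------------------------------------------------------------------
# Hill-type drug effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEffect:
    """One Hill-type concentration-dependent scaling of a preset parameter.

    The scale applied at concentration ``c`` (μM) is
    ``1 ± emax * c**h / (c**h + ec50**h)`` with the sign set by ``direction``.
    """

    target: str                   # one of EFFECT_TARGETS
    direction: str                # "increase" | "decrease"
    emax: float                   # max fractional change, >= 0
    ec50: float                   # μM, > 0
    hill_coefficient: float = 1.0
    fractions: tuple[float, ...] | None = None  # apd_scale only: subset of fractions

    def __post_init__(self):
        if self.target not in EFFECT_TARGETS:
            raise InvalidConfigError(f"unknown effect target {self.target!r}")
        if self.direction not in ("increase", "decrease"):
            raise InvalidConfigError(f"direction must be increase/decrease, got {self.direction!r}")
        if self.emax < 0:
            raise InvalidConfigError("emax must be non-negative")
        if self.ec50 <= 0:
            raise InvalidConfigError("ec50 must be positive")
        if self.hill_coefficient <= 0:
            raise InvalidConfigError("hill_coefficient must be positive")

    def occupancy(self, concentration: float) -> float:
        """Hill term c^h / (c^h + EC50^h); 0 at c = 0, 1/2 at c = EC50."""
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        if concentration == 0:
            return 0.0
        h = self.hill_coefficient
        ch = concentration ** h
        return ch / (ch + self.ec50 ** h)

    def scale(self, concentration: float) -> float:
        sign = 1.0 if self.direction == "increase" else -1.0
        return 1.0 + sign * self.emax * self.occupancy(concentration)


@dataclass(frozen=True)
class DrugEffectModel:
    """A drug's parameter effects plus the arrhythmia-event incidences to emulate.

    ``event_incidence`` maps (concentration μM, group) to expected fractions of
    wells exhibiting each event class, e.g. ``{(10.0, "CT"): {"ead": 1/3, "arrest": 2/3}}``.
    """

    drug_name: str
    effects: tuple[DrugEffect, ...] = ()
    event_incidence: tuple[tuple[tuple[float, str], tuple[tuple[str, float], ...]], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        norm = []
        for key, fracs in self.event_incidence:
            conc, group = key
            fracs = tuple((str(k), float(v)) for k, v in dict(fracs).items())
            total = 0.0
            for kind, frac in fracs:
                if kind not in ("irregular", "ead", "arrest"):
                    raise InvalidConfigError(f"unknown event kind {kind!r}")
                if not 0.0 <= frac <= 1.0:
                    raise InvalidConfigError(f"event fraction {frac} outside [0, 1]")
                total += frac
            if total > 1.0 + 1e-9:
                raise InvalidConfigError(
                    f"event fractions for {(conc, group)} sum to {total:.3f} > 1"
                )
            norm.append(((float(conc), str(group)), fracs))
        object.__setattr__(self, "event_incidence", tuple(norm))

    def incidence(self, concentration: float, group: str) -> dict[str, float]:
        for (conc, grp), fracs in self.event_incidence:
            if grp == group and np.isclose(conc, concentration):
                return dict(fracs)
        return {}


def apply_drug_effect(preset: PhenotypePreset, model: DrugEffectModel,
                      concentration: float) -> PhenotypePreset:
    """Return a copy of ``preset`` with the model's Hill scalings applied.

    Concentration 0 returns the preset unchanged; every targeted parameter is
    monotone in concentration.  Raises :class:`InvalidConfigError` if the
    scaled targets would violate the preset invariants (e.g. overlap the IBI).
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rate = preset.beat_rate
    tau_up = preset.upstroke_time_constant
    targets = preset.targets()
    for eff in model.effects:
        s = eff.scale(concentration)
        if eff.target == "beat_rate":
            rate *= s
        elif eff.target == "upstroke_velocity_scale":
            # faster upstroke -> smaller logistic time constant
            tau_up /= s
        elif eff.target == "decay_velocity_scale":
            # faster repolarization -> uniformly shorter durations
            targets = {f: v / s for f, v in targets.items()}
        elif eff.target == "apd_scale":
            which = eff.fractions or tuple(targets)
            targets = {f: (v * s if f in which else v) for f, v in targets.items()}
    return replace(
        preset,
        beat_rate=rate,
        upstroke_time_constant=tau_up,
        apd_targets=_as_target_items(targets),
    )
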