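"""Synthetic plate-format optical action-potential traces with ground truth.

Each simulated well draws its beats from a calibrated single-beat template
(:mod:`apscreen.waveform`) placed at jittered onsets, on top of a baseline
with linear photobleaching drift, plus i.i.d. Gaussian measurement noise.
Arrhythmia-like events — early afterdepolarization (EAD) bumps, irregular
beating, and arrest — can be injected with full ground-truth bookkeeping.

Randomness is organised as independent counter-based streams per well
(``SeedSequence((seed, k))`` with k = 0 beat onsets, 1 noise, 2 events), so
injecting an event never perturbs the onset or noise draws of the same well:
an irregular injection with CV 0 reproduces the uninjected trace bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

from ._errors import InvalidConfigError
from .io import Trace, write_traces
from .presets import (
    DEFAULT_PRESETS,
    DrugEffect,
    DrugEffectModel,
    PhenotypePreset,
    apply_drug_effect,
)
from .waveform import calibrated

EVENT_KINDS = ("none", "ead", "irregular", "arrest")

_ONSET_STREAM, _NOISE_STREAM, _EVENT_STREAM = 0, 1, 2
_Z_BLOCK = 4096
_IBI_CLIP = (0.6, 1.8)   # relative clip on jittered inter-beat intervals


@dataclass(frozen=True)
class EventSpec:
    """An arrhythmia-like event to inject into a well."""

    kind: str = "none"
    bump_frac: float = 0.10      # EAD: secondary-maximum prominence as fraction of amplitude
    phase_frac: float = 0.50     # EAD: repolarization fraction at which the bump sits
    beat_frac: float = 1.0       # EAD: fraction of beats affected
    width_ms: float = 12.0       # EAD: Gaussian bump SD
    cv: float = 0.30             # irregular: requested IBI coefficient of variation
    onset_s: float = 0.0         # arrest: cessation time

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise InvalidConfigError(f"unknown event kind {self.kind!r}")
        if self.kind == "ead":
            if not 0.0 < self.bump_frac < 1.0:
                raise InvalidConfigError("EAD bump_frac must be in (0, 1)")
            if not 0.3 < self.phase_frac < 0.9:
                raise InvalidConfigError("EAD phase_frac must be in (0.3, 0.9)")
            if not 0.0 < self.beat_frac <= 1.0:
                raise InvalidConfigError("EAD beat_frac must be in (0, 1]")
        if self.kind == "irregular" and self.cv < 0:
            raise InvalidConfigError("irregular cv must be non-negative")
        if self.kind == "arrest" and self.onset_s < 0:
            raise InvalidConfigError("arrest onset must be non-negative")


NO_EVENT = EventSpec()


@dataclass
class GroundTruth:
    """Everything a test oracle needs to know about one simulated trace."""

    well_id: str
    preset: PhenotypePreset
    phase: str | None
    seed: int
    duration_s: float
    sampling_interval_ms: float
    event: EventSpec
    activation_times: np.ndarray        # s, realized beat activations
    ibis: np.ndarray                    # s, realized inter-activation intervals
    rate_true: float                    # beats/min (preset, post-effect)
    amplitude_true: float
    apd_true: dict[float, float]        # ms, uncorrected
    capd_true: dict[float, float]       # ms, Fridericia-corrected at the preset rate
    v_up_true: float                    # units/s on the acquisition grid
    v_down_true: float
    concentration: float | None = None
    drug: str | None = None

    @property
    def n_beats(self) -> int:
        return int(len(self.activation_times))

    @property
    def ibi_cv(self) -> float:
        if len(self.ibis) < 2:
            return 0.0
        return float(np.std(self.ibis, ddof=1) / np.mean(self.ibis))

    def to_row(self) -> dict:
        row = {
            "well": self.well_id, "phase": self.phase, "preset": self.preset.name,
            "drug": self.drug or "none", "concentration_uM": self.concentration,
            "seed": self.seed, "rate_true": self.rate_true,
            "amplitude_true": self.amplitude_true,
            "v_up_true": self.v_up_true, "v_down_true": self.v_down_true,
            "n_beats_true": self.n_beats, "ibi_cv_true": self.ibi_cv,
            "event": self.event.kind,
            "ead_bump_frac": self.event.bump_frac if self.event.kind == "ead" else np.nan,
            "ead_phase_frac": self.event.phase_frac if self.event.kind == "ead" else np.nan,
            "irregular_cv": self.event.cv if self.event.kind == "irregular" else np.nan,
            "arrest_onset_s": self.event.onset_s if self.event.kind == "arrest" else np.nan,
        }
        for f, v in self.apd_true.items():
            row[f"apd{int(round(f * 100))}_ms"] = v
        for f, v in self.capd_true.items():
            row[f"capd{int(round(f * 100))}_ms"] = v
        return row


def _stream(seed: int, k: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), k))))


@lru_cache(maxsize=128)
def _ead_gauss_height(preset: PhenotypePreset, phase_frac: float, width_ms: float,
                      bump_frac: float) -> float:
    """Gaussian height whose noise-free secondary prominence equals ``bump_frac``.

    A Gaussian deflection riding on a repolarizing limb loses part of its
    height to the local decay slope before it shows up as a local maximum.
    The injected EAD is therefore calibrated so that the *realized*
    secondary-maximum prominence on the clean beat — the quantity an EAD
    detector sees — equals the requested fraction of the beat amplitude.
    """
    tpl = calibrated(preset).template
    t, y = tpl.t, tpl.y  # normalized: baseline 0, peak 1
    c = tpl.t_act + preset.apd(phase_frac) / 1000.0
    sd = width_ms / 1000.0
    g = np.exp(-0.5 * ((t - c) / sd) ** 2)
    p_idx = int(np.argmax(y))

    def prominence(h: float) -> float:
        z = y + h * g
        after = z[p_idx:]
        lo = np.flatnonzero(after <= 0.70)
        hi = np.flatnonzero(after <= 0.05)
        i0 = p_idx + (int(lo[0]) if lo.size else 0)
        i1 = p_idx + (int(hi[0]) if hi.size else after.size)
        if i1 - i0 < 3:
            return 0.0
        pk, pr = find_peaks(z[i0:i1], prominence=0.0)
        return float(pr["prominences"].max()) if pk.size else 0.0

    h = bump_frac
    for _ in range(25):
        err = bump_frac - prominence(h)
        if abs(err) < 1e-4:
            break
        h = float(np.clip(h + err, 1e-4, 0.95))
    return h


def _sampled_beat_slopes(preset: PhenotypePreset, dt_ms: float) -> tuple[float, float]:
    """Raw-first-difference slopes of the clean beat on the acquisition grid.

    Rendered beats start at arbitrary fractional grid offsets, so the
    expected maximal secant slope is averaged over the grid phase.
    """
    tpl = calibrated(preset).template
    dt = dt_ms / 1000.0
    ups, downs = [], []
    for phase in np.linspace(0.0, dt, 8, endpoint=False):
        tt = np.arange(phase, tpl.duration_s, dt)
        yy = np.interp(tt, tpl.t, tpl.y) * preset.amplitude
        d = np.diff(yy) / dt
        ups.append(d.max())
        downs.append(-d.min())
    return float(np.mean(ups)), float(np.mean(downs))


def generate_trace(preset: PhenotypePreset, duration: float = 30.0,
                   sampling_interval: float = 5.0, seed: int = 0, *,
                   well_id: str = "A1", phase: str | None = None,
                   drug: str | None = None, concentration: float | None = None,
                   event: EventSpec = NO_EVENT) -> tuple[Trace, GroundTruth]:
    """Simulate one well's fluorescence trace.

    ``duration`` in seconds (>= 30 s recommended, the analysis window);
    ``sampling_interval`` in ms (5 or 10 typical; any positive value works).
    Identical arguments produce bitwise-identical traces.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be positive, got {sampling_interval}")
    if event.kind == "arrest" and event.onset_s > duration:
        raise ValueError(
            f"arrest onset {event.onset_s} s lies beyond the trace end ({duration} s)")

    tpl = calibrated(preset).template
    dt = sampling_interval / 1000.0
    n = int(math.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt

    # --- beat onsets -------------------------------------------------------
    z = _stream(seed, _ONSET_STREAM).standard_normal(_Z_BLOCK)
    cv = preset.rate_jitter_cv
    if event.kind == "irregular":
        cv = math.hypot(cv, event.cv)
    rel = np.clip(1.0 + cv * z, *_IBI_CLIP)
    ibis_pool = preset.ibi_s * rel

    lead = tpl.t_act
    post = tpl.post_activation_s
    acts = []
    a = lead + 0.04
    k = 0
    while a + post <= duration and k < _Z_BLOCK:
        acts.append(a)
        a += ibis_pool[k]
        k += 1
    acts = np.asarray(acts)
    if event.kind == "arrest":
        acts = acts[acts < event.onset_s]

    # --- deterministic signal ---------------------------------------------
    amp = preset.amplitude
    drift = preset.drift_rate * amp / 60.0   # units per second
    clean = np.full(n, preset.baseline_level) - drift * t
    amp_at = lambda a0: amp * max(1.0 - preset.drift_rate * a0 / 60.0, 0.2)
    for a0 in acts:
        start = a0 - lead
        i0 = max(int(math.ceil(start / dt - 1e-9)), 0)
        i1 = min(int(math.floor((start + tpl.duration_s) / dt + 1e-9)) + 1, n)
        if i1 <= i0:
            continue
        clean[i0:i1] += amp_at(a0) * np.interp(t[i0:i1] - start, tpl.t, tpl.y)

    if event.kind == "ead" and len(acts):
        if event.beat_frac >= 1.0:
            affected = np.arange(len(acts))
        else:
            n_aff = max(int(round(event.beat_frac * len(acts))), 1)
            affected = np.sort(
                _stream(seed, _EVENT_STREAM).choice(len(acts), size=n_aff, replace=False))
        t_bump = preset.apd(event.phase_frac) / 1000.0
        sd = event.width_ms / 1000.0
        height = _ead_gauss_height(preset, event.phase_frac, event.width_ms,
                                   event.bump_frac)
        for idx in affected:
            c = acts[idx] + t_bump
            j0 = max(int((c - 4 * sd) / dt), 0)
            j1 = min(int((c + 4 * sd) / dt) + 1, n)
            clean[j0:j1] += (height * amp_at(acts[idx])
                             * np.exp(-0.5 * ((t[j0:j1] - c) / sd) ** 2))

    noise = _stream(seed, _NOISE_STREAM).standard_normal(n) * preset.noise_sd * amp
    signal = clean + noise

    trace = Trace(well_id=well_id, time=t, signal=signal,
                  sampling_interval=sampling_interval, group=preset.name,
                  drug=drug, concentration=concentration, phase=phase)
    ibis = np.diff(acts)
    v_up, v_down = _sampled_beat_slopes(preset, sampling_interval)
    gt = GroundTruth(
        well_id=well_id, preset=preset, phase=phase, seed=int(seed),
        duration_s=duration, sampling_interval_ms=sampling_interval, event=event,
        activation_times=acts, ibis=ibis, rate_true=preset.beat_rate,
        amplitude_true=amp, apd_true=preset.targets(),
        capd_true=preset.corrected_targets(), v_up_true=v_up, v_down_true=v_down,
        drug=drug, concentration=concentration,
    )
    return trace, gt


def inject_event(trace: Trace, ground_truth: GroundTruth, event: EventSpec,
                 ) -> tuple[Trace, GroundTruth]:
    """Re-render a simulated trace with ``event`` injected.

    Because all random draws flow from fixed per-well streams, the baseline,
    noise, and (for EAD/arrest) the beat onsets are identical to the
    uninjected trace; only the event's own footprint changes.
    """
    gt = ground_truth
    return generate_trace(
        gt.preset, duration=gt.duration_s, sampling_interval=gt.sampling_interval_ms,
        seed=gt.seed, well_id=gt.well_id, phase=gt.phase, drug=gt.drug,
        concentration=gt.concentration, event=event,
    )


# ---------------------------------------------------------------------------
# Plate-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellSpec:
    """One (well, phase) entry of a plate simulation config."""

    well: str
    group: str
    phase: str = "post"
    drug: str = "none"
    concentration: float = 0.0
    seed: int = 0
    event: EventSpec = NO_EVENT


@dataclass
class PlateConfig:
    duration_s: float = 30.0
    sampling_interval_ms: float = 5.0
    wells: list[WellSpec] = field(default_factory=list)
    drugs: dict[str, DrugEffectModel] = field(default_factory=dict)
    presets: dict[str, PhenotypePreset] = field(default_factory=lambda: dict(DEFAULT_PRESETS))


@dataclass
class PlateSim:
    """In-memory result of :func:`generate_plate`."""

    traces: dict[str, dict[str, Trace]]            # phase -> well -> Trace
    ground_truth: dict[tuple[str, str], GroundTruth]  # (well, phase) -> GT
    trace_frames: dict[str, pd.DataFrame]          # phase -> wide CSV frame
    plate_map: pd.DataFrame
    ground_truth_frame: pd.DataFrame


def generate_plate(config: PlateConfig, out_dir: str | Path | None = None) -> PlateSim:
    """Simulate every well of a plate config; optionally write the CSV files.

    Emits (when ``out_dir`` is given) ``traces_pre.csv`` / ``traces_post.csv``,
    ``plate_map.csv`` and ``ground_truth.csv``.  Wells are independent given
    their seeds.  Duplicate (well, phase) entries are an error.
    """
    seen = set()
    for ws in config.wells:
        key = (ws.well, ws.phase)
        if key in seen:
            raise InvalidConfigError(f"duplicate well entry {key}")
        seen.add(key)

    dt = config.sampling_interval_ms / 1000.0
    n = int(math.floor(config.duration_s / dt + 1e-9)) + 1
    time = np.arange(n) * dt

    traces: dict[str, dict[str, Trace]] = {}
    gts: dict[tuple[str, str], GroundTruth] = {}
    map_rows, gt_rows = [], []
    for ws in config.wells:
        if ws.group not in config.presets:
            raise InvalidConfigError(f"well {ws.well}: unknown group {ws.group!r}")
        preset = config.presets[ws.group]
        drug = None if ws.drug in ("none", "", None) else ws.drug
        if ws.phase == "post" and drug is not None and drug in config.drugs:
            preset = apply_drug_effect(preset, config.drugs[drug], ws.concentration)
        tr, gt = generate_trace(
            preset, duration=config.duration_s,
            sampling_interval=config.sampling_interval_ms, seed=ws.seed,
            well_id=ws.well, phase=ws.phase, drug=drug,
            concentration=ws.concentration, event=ws.event if ws.phase == "post" else NO_EVENT,
        )
        tr.group = ws.group
        traces.setdefault(ws.phase, {})[ws.well] = tr
        gts[(ws.well, ws.phase)] = gt
        map_rows.append({
            "well": ws.well, "group": ws.group, "drug": ws.drug or "none",
            "concentration_uM": ws.concentration, "phase": ws.phase, "seed": ws.seed,
        })
        gt_rows.append(gt.to_row())

    frames = {}
    for phase in ("pre", "post"):
        if phase not in traces and not any(ws.phase == phase for ws in config.wells):
            continue
        data = {"time_s": time}
        for well in sorted(traces.get(phase, {})):
            data[well] = traces[phase][well].signal
        frames[phase] = pd.DataFrame(data)
    if not frames:  # degenerate empty config: still a valid time-only CSV
        frames["post"] = pd.DataFrame({"time_s": time})

    plate_map = pd.DataFrame(
        map_rows, columns=["well", "group", "drug", "concentration_uM", "phase", "seed"])
    gt_frame = pd.DataFrame(gt_rows)

    sim = PlateSim(traces=traces, ground_truth=gts, trace_frames=frames,
                   plate_map=plate_map, ground_truth_frame=gt_frame)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_traces(frames, out)
        plate_map.to_csv(out / "plate_map.csv", index=False)
        gt_frame.to_csv(out / "ground_truth.csv", index=False)
    return sim


# ---------------------------------------------------------------------------
# Reference fixtures for the published incidence narratives
# ---------------------------------------------------------------------------

def condition_fixture(condition: str, duration_s: float = 30.0,
                      sampling_interval_ms: float = 5.0) -> PlateConfig:
    """Plate configs emulating the published per-condition event incidences.

    ``donepezil_ct_10um``   — 6 CT wells: 2 EAD-injected, 4 arrest-injected.
    ``propranolol_am_10um`` — 9 AM wells: 1 irregular-injected (IBI CV 0.30).
    ``carbamazepine_ct_100um`` — 12 CT wells: 11 arrest-injected.

    Wells are seeded 1..n; every well gets a matching untreated pre phase.
    """
    ead = EventSpec(kind="ead", bump_frac=0.10, phase_frac=0.50, beat_frac=1.0)
    arrest = EventSpec(kind="arrest", onset_s=0.0)
    irregular = EventSpec(kind="irregular", cv=0.30)
    plans = {
        "donepezil_ct_10um": ("CT", "donepezil", 10.0, [ead] * 2 + [arrest] * 4),
        "propranolol_am_10um": ("AM", "propranolol", 10.0, [irregular] + [NO_EVENT] * 8),
        "carbamazepine_ct_100um": ("CT", "carbamazepine", 100.0, [arrest] * 11 + [NO_EVENT]),
    }
    if condition not in plans:
        raise InvalidConfigError(
            f"unknown condition {condition!r}; choose from {sorted(plans)}")
    group, drug, conc, events = plans[condition]
    wells = []
    for i, ev in enumerate(events, start=1):
        wid = f"A{i}" if i <= 12 else f"B{i - 12}"
        wells.append(WellSpec(well=wid, group=group, phase="pre", drug=drug,
                              concentration=0.0, seed=i))
        wells.append(WellSpec(well=wid, group=group, phase="post", drug=drug,
                              concentration=conc, seed=i, event=ev))
    return PlateConfig(duration_s=duration_s, sampling_interval_ms=sampling_interval_ms,
                       wells=wells)


# ---------------------------------------------------------------------------
# YAML config loading (CLI `simulate`)
# ---------------------------------------------------------------------------

def load_plate_config(path: str | Path) -> PlateConfig:
    """Load a plate simulation config from a YAML file.

    Schema::

        duration_s: 30
        sampling_interval_ms: 5
        drugs:                      # optional Hill-type effect models
          drugX:
            effects:
              - {target: apd_scale, direction: increase,
                 emax: 0.3, ec50: 1.0, hill: 1.0}
        wells:
          - {well: A1, group: CT, drug: drugX, concentration_uM: 10,
             phase: post, seed: 1, event: ead, bump_frac: 0.1, phase_frac: 0.5}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    drugs = {}
    for name, spec in (raw.get("drugs") or {}).items():
        effects = tuple(
            DrugEffect(
                target=e["target"], direction=e["direction"], emax=float(e["emax"]),
                ec50=float(e["ec50"]), hill_coefficient=float(e.get("hill", 1.0)),
            )
            for e in spec.get("effects", [])
        )
        drugs[name] = DrugEffectModel(drug_name=name, effects=effects)
    wells = []
    for w in raw.get("wells") or []:
        kind = w.get("event", "none")
        ev_kwargs = {k: float(w[k]) for k in
                     ("bump_frac", "phase_frac", "beat_frac", "width_ms", "cv", "onset_s")
                     if k in w}
        wells.append(WellSpec(
            well=str(w["well"]), group=str(w["group"]), phase=str(w.get("phase", "post")),
            drug=str(w.get("drug", "none")), concentration=float(w.get("concentration_uM", 0.0)),
            seed=int(w.get("seed", 0)), event=EventSpec(kind=kind, **ev_kwargs),
        ))
    return PlateConfig(
        duration_s=float(raw.get("duration_s", 30.0)),
        sampling_interval_ms=float(raw.get("sampling_interval_ms", 5.0)),
        wells=wells, drugs=drugs,
    )
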