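"""Arrhythmia-like event calling: EAD, irregular beating, arrest.

Each well's post-compound recording receives exactly one label, with the
priority arrest > EAD > irregular > normal — a well that stopped beating is
an arrest even if earlier beats carried afterdepolarizations.

The individual detectors are deliberately simple and threshold-based, with
all thresholds exposed in :class:`ClassifierThresholds`:

* EAD: a secondary local maximum on the repolarization limb (searched
  between the 30% and 95% decay levels) with prominence >= 5% of the beat
  amplitude and width >= 2 samples;
* irregular: coefficient of variation of the inter-beat intervals > 0.15
  (scale-free, so the same rule serves both slow and fast phenotypes);
  undefined below 5 beats;
* arrest: <= 1 detected beat in the 30-s analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .beats import Beat, WellSummary, smooth_signal
from .io import Trace

LABELS = ("normal", "irregular", "EAD", "arrest")


@dataclass(frozen=True)
class ClassifierThresholds:
    ead_prominence_frac: float = 0.05   # fraction of beat amplitude
    ead_band: tuple[float, float] = (0.30, 0.95)  # decay-fraction search band
    ead_min_width_samples: int = 2
    irregular_cv_threshold: float = 0.15
    irregular_min_beats: int = 5
    arrest_max_beats: int = 1


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass
class EventCall:
    """The label assigned to one well plus the evidence behind it."""

    well_id: str
    label: str
    ibi_cv: float = np.nan
    n_ead_beats: int = 0
    n_beats: int = 0
    max_secondary_prominence: float = 0.0  # fraction of amplitude
    irregular_evaluable: bool = True


def _aligned_ensemble(y: np.ndarray, beats: list[Beat], t0: float, dt: float,
                      ) -> tuple[np.ndarray | None, int, list[int]]:
    """Median beat waveform aligned on activation; noise shrinks ~1/sqrt(n)."""
    acts = [int(round((b.t_activation - t0) / dt)) for b in beats]
    lead = int(round(0.020 / dt))
    if len(acts) >= 2:
        seg_len = int(np.median(np.diff(acts)))
    else:
        seg_len = len(y) - acts[0]
    seg_len = min(seg_len, len(y) - max(acts[0] - lead, 0))
    segs, used = [], []
    for j, a in enumerate(acts):
        i0 = a - lead
        if i0 < 0 or i0 + seg_len > len(y):
            continue
        segs.append(y[i0:i0 + seg_len])
        used.append(j)
    if not segs:
        return None, lead, []
    return np.median(np.vstack(segs), axis=0), lead, used


def detect_ead(trace: Trace, beats: list[Beat],
               thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
               ) -> tuple[list[bool], float]:
    """Flag beats whose repolarization limb carries a secondary maximum.

    A single beat's bump competes with measurement noise at only a few sigma,
    so the decision is pooled: the beats of the well are aligned on their
    activation times and reduced to a median beat, whose repolarization limb
    (between the 30% and 95% decay levels) is searched for a local maximum
    with prominence >= ``ead_prominence_frac`` of the beat amplitude and
    width >= 2 samples.  When the median beat tests positive, individual
    beats are flagged by a confirmatory local-maximum check (half prominence)
    around the ensemble bump position.

    Returns per-beat flags and the largest secondary prominence on the median
    beat (as a fraction of the mean beat amplitude).
    """
    if not beats:
        return [], 0.0
    # the ensemble median suppresses noise by pooling beats, so it is built
    # from the raw signal: pre-smoothing would shave the bump's prominence
    y_raw = trace.signal
    y = smooth_signal(y_raw, trace.sampling_interval)
    t0 = float(trace.time[0])
    dt = trace.dt_s
    lo_frac, hi_frac = thresholds.ead_band
    amp = float(np.mean([b.amplitude for b in beats]))
    base = float(np.mean([b.baseline for b in beats]))

    ens, lead, used = _aligned_ensemble(y_raw, beats, t0, dt)
    flags = [False] * len(beats)
    if ens is None or ens.size < lead + 5:
        return flags, 0.0
    p_ens = lead + int(np.argmax(ens[lead:min(lead + max(int(0.1 / dt), 5), ens.size)]))
    lo_level = base + (1.0 - lo_frac) * amp
    hi_level = base + (1.0 - hi_frac) * amp
    after = ens[p_ens:]
    below_lo = np.flatnonzero(after <= lo_level)
    i0 = p_ens + (int(below_lo[0]) if below_lo.size else 0)
    below_hi = np.flatnonzero(after <= hi_level)
    i1 = p_ens + (int(below_hi[0]) if below_hi.size else after.size)
    if i1 - i0 < 3:
        return flags, 0.0
    seg = ens[i0:i1]
    peaks, props = find_peaks(seg, prominence=thresholds.ead_prominence_frac * amp,
                              width=thresholds.ead_min_width_samples)
    all_peaks, all_props = find_peaks(seg, prominence=0.0)
    max_prom = float(all_props["prominences"].max() / amp) if all_peaks.size else 0.0
    if not peaks.size:
        return flags, max_prom

    # confirm per beat around the ensemble bump position (offset from activation)
    bump_off = i0 - lead + int(peaks[np.argmax(props["prominences"])])
    win = max(int(round(0.030 / dt)), 2)
    best_j, best_prom = None, -1.0
    acts = [int(round((b.t_activation - t0) / dt)) for b in beats]
    for j, a in enumerate(acts):
        c0 = max(a + bump_off - win, 0)
        c1 = min(a + bump_off + win + 1, len(y))
        if c1 - c0 < 3:
            continue
        pk, pr = find_peaks(y[c0:c1],
                            prominence=0.5 * thresholds.ead_prominence_frac * amp)
        if pk.size:
            flags[j] = True
            prom = float(pr["prominences"].max())
            if prom > best_prom:
                best_j, best_prom = j, prom
    if not any(flags) and best_j is None and beats:
        # the ensemble is unambiguous; attribute it to the closest single beat
        flags[int(np.argmax([b.amplitude for b in beats]))] = True
    return flags, max_prom


def detect_irregular(beats: list[Beat],
                     thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                     ) -> tuple[bool | None, float]:
    """Irregular-beating flag from the IBI coefficient of variation.

    Returns ``(None, nan)`` when fewer than ``irregular_min_beats`` beats are
    available — irregularity is then not evaluable.
    """
    ibis = np.array([b.ibi_prev for b in beats if b.ibi_prev is not None], float)
    if len(beats) < thresholds.irregular_min_beats or ibis.size < 2:
        return None, np.nan
    cv = float(ibis.std(ddof=1) / ibis.mean())
    return cv > thresholds.irregular_cv_threshold, cv


def detect_arrest(summary: WellSummary,
                  thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Cessation of beating: at most ``arrest_max_beats`` beats in the window."""
    return summary.n_beats <= thresholds.arrest_max_beats


def classify_well(trace: Trace, beats: list[Beat], summary: WellSummary,
                  thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> EventCall:
    """Assign exactly one label per well, priority arrest > EAD > irregular > normal."""
    call = EventCall(well_id=summary.well_id or trace.well_id, label="normal",
                     n_beats=summary.n_beats)
    w0, w1 = summary.window
    window_beats = [b for b in beats if w0 <= b.t_activation <= w1]
    if detect_arrest(summary, thresholds):
        call.label = "arrest"
        return call
    flags, max_prom = detect_ead(trace, window_beats, thresholds)
    call.n_ead_beats = int(sum(flags))
    call.max_secondary_prominence = max_prom
    irr, cv = detect_irregular(window_beats, thresholds)
    call.ibi_cv = cv
    call.irregular_evaluable = irr is not None
    if call.n_ead_beats >= 1:
        call.label = "EAD"
    elif irr:
        call.label = "irregular"
    return call


def incidence_table(calls: list[EventCall], metadata: pd.DataFrame) -> pd.DataFrame:
    """Count labels per (drug, group, concentration) condition.

    ``metadata`` must carry one row per well with columns
    ``well, group, drug, concentration_uM``.  Returns the documented
    ``incidence.csv`` shape with deterministic row order (drug, group,
    ascending concentration); denominators equal the wells analyzed.
    """
    by_well = {c.well_id: c for c in calls}
    meta = metadata.drop_duplicates(subset="well").copy()
    missing = set(by_well) - set(meta["well"])
    if missing:
        raise KeyError(f"wells without condition metadata: {sorted(missing)}")
    meta = meta[meta["well"].isin(by_well)]
    meta["label"] = meta["well"].map(lambda w: by_well[w].label)
    rows = []
    for (drug, group, conc), g in meta.groupby(["drug", "group", "concentration_uM"],
                                               dropna=False):
        rows.append({
            "drug": drug, "group": group, "concentration_uM": conc, "n": len(g),
            "n_irregular": int((g["label"] == "irregular").sum()),
            "n_ead": int((g["label"] == "EAD").sum()),
            "n_arrest": int((g["label"] == "arrest").sum()),
        })
    out = pd.DataFrame(rows, columns=["drug", "group", "concentration_uM", "n",
                                      "n_irregular", "n_ead", "n_arrest"])
    return out.sort_values(["drug", "group", "concentration_uM"]).reset_index(drop=True)
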