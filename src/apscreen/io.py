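"""Reading and writing plate trace CSVs, plate maps, and results tables.

On-disk formats
---------------
Trace file (one per recording phase, ``traces_pre.csv`` / ``traces_post.csv``):
    wide CSV, header ``time_s,<wellID>,...``; time strictly increasing on a
    uniform grid (seconds); one column of fluorescence values per well.

Plate map (``plate_map.csv``):
    columns ``well,group,drug,concentration_uM,phase,seed`` — one row per
    (well, phase).  ``drug`` empty or ``none`` for untreated wells.

Results:
    ``well_summary.csv`` (one row per well and phase),
    ``dose_response.csv`` (drug, group, concentration_uM, parameter,
    mean_pct, sd_pct, n), ``incidence.csv`` (drug, group, concentration_uM,
    n, n_irregular, n_ead, n_arrest), ``stats.csv``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import FormatError, MappingError

PHASES = ("pre", "post")
GROUPS = ("CT", "AM")

_REL_STEP_TOL = 1e-6


@dataclass
class Trace:
    """One well's fluorescence time series plus its plate-map annotations."""

    well_id: str
    time: np.ndarray          # seconds, uniform grid
    signal: np.ndarray        # arbitrary fluorescence units
    sampling_interval: float  # ms
    group: str | None = None  # "CT" | "AM"
    drug: str | None = None
    concentration: float | None = None  # μM
    phase: str | None = None  # "pre" | "post"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise FormatError(f"well {self.well_id}: time and signal must be 1-D and equal length")
        if self.time.size < 2:
            raise FormatError(f"well {self.well_id}: trace needs at least 2 samples")
        steps = np.diff(self.time)
        step = float(np.median(steps))
        if step <= 0 or np.any(np.abs(steps - step) > _REL_STEP_TOL * max(step, 1e-12)):
            raise FormatError(f"well {self.well_id}: time grid is not uniform and increasing")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError(f"well {self.well_id}: signal contains non-finite values")
        expected = step * 1000.0
        if not np.isclose(self.sampling_interval, expected, rtol=1e-4):
            raise FormatError(
                f"well {self.well_id}: sampling_interval {self.sampling_interval} ms "
                f"disagrees with time grid step {expected:.6g} ms"
            )

    @property
    def dt_s(self) -> float:
        return self.sampling_interval / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy_with(self, signal: np.ndarray) -> "Trace":
        return Trace(
            well_id=self.well_id, time=self.time.copy(), signal=np.asarray(signal, float),
            sampling_interval=self.sampling_interval, group=self.group, drug=self.drug,
            concentration=self.concentration, phase=self.phase,
        )


@dataclass
class PlateRecording:
    """All traces of one plate, paired pre/post per well."""

    wells: dict[str, dict[str, Trace]] = field(default_factory=dict)  # well -> phase -> Trace
    sampling_interval: float | None = None  # ms
    duration_s: float | None = None

    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    def trace(self, well_id: str, phase: str) -> Trace:
        return self.wells[well_id][phase]

    def validate_pairing(self) -> None:
        """Every post trace must have a matching pre trace (percent change needs it)."""
        missing = [w for w, ph in self.wells.items() if "post" in ph and "pre" not in ph]
        if missing:
            raise MappingError(
                f"post-phase traces without a matching pre-phase trace: {sorted(missing)}"
            )


def read_plate_map(plate_map_path: str | os.PathLike) -> pd.DataFrame:
    pm = pd.read_csv(plate_map_path, dtype={"well": str, "group": str, "drug": str, "phase": str})
    required = {"well", "group", "drug", "concentration_uM", "phase", "seed"}
    missing = required - set(pm.columns)
    if missing:
        raise FormatError(f"plate map missing columns: {sorted(missing)}")
    bad_phase = set(pm["phase"]) - set(PHASES)
    if bad_phase:
        raise FormatError(f"plate map has unknown phases: {sorted(bad_phase)}")
    dup = pm.duplicated(subset=["well", "phase"])
    if dup.any():
        raise FormatError(
            f"plate map has duplicate (well, phase) rows: "
            f"{pm.loc[dup, ['well', 'phase']].to_records(index=False).tolist()}"
        )
    pm["drug"] = pm["drug"].fillna("none")
    return pm


def _read_trace_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    return df


def read_plate(trace_csvs: Mapping[str, str | os.PathLike] | str | os.PathLike,
               plate_map_path: str | os.PathLike) -> PlateRecording:
    """Load a plate recording from per-phase trace CSVs and a plate map.

    ``trace_csvs`` is either a mapping ``{"pre": path, "post": path}`` (either
    phase may be absent) or a directory containing ``traces_pre.csv`` and/or
    ``traces_post.csv``.

    Raises :class:`FormatError` for malformed files and :class:`MappingError`
    when the trace files and plate map disagree about which wells exist.
    """
    if isinstance(trace_csvs, (str, os.PathLike)):
        d = Path(trace_csvs)
        if not d.is_dir():
            raise FormatError(f"{d} is not a directory; pass a {{phase: path}} mapping instead")
        trace_csvs = {
            ph: d / f"traces_{ph}.csv" for ph in PHASES if (d / f"traces_{ph}.csv").exists()
        }
        if not trace_csvs:
            raise FormatError(f"no traces_pre.csv / traces_post.csv found in {d}")

    pm = read_plate_map(plate_map_path)
    rec = PlateRecording()
    for phase, path in trace_csvs.items():
        if phase not in PHASES:
            raise FormatError(f"unknown phase {phase!r}")
        df = _read_trace_csv(path)
        time = df["time_s"].to_numpy(float)
        phase_map = pm[pm["phase"] == phase].set_index("well")
        for well in df.columns[1:]:
            if well not in phase_map.index:
                raise MappingError(
                    f"well {well!r} present in {path} but absent from the plate map "
                    f"(phase {phase!r})"
                )
            row = phase_map.loc[well]
            conc = row["concentration_uM"]
            step = float(np.median(np.diff(time))) if time.size > 1 else np.nan
            tr = Trace(
                well_id=well, time=time, signal=df[well].to_numpy(float),
                sampling_interval=step * 1000.0,
                group=row["group"], drug=None if row["drug"] in ("none", "") else row["drug"],
                concentration=None if pd.isna(conc) else float(conc),
                phase=phase,
            )
            rec.wells.setdefault(well, {})[phase] = tr
        rec.sampling_interval = step * 1000.0
        rec.duration_s = float(time[-1] - time[0])
    rec.validate_pairing()
    return rec


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_traces(traces: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write per-phase wide trace CSVs (``traces_<phase>.csv``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for phase, df in traces.items():
        p = out / f"traces_{phase}.csv"
        df.to_csv(p, index=False)
        paths[phase] = p
    return paths


WELL_SUMMARY_COLUMNS = [
    "well", "phase", "group", "drug", "concentration_uM", "n_beats", "beat_rate",
    "amplitude_mean", "v_up_mean", "v_down_mean", "v_up_norm_mean", "v_down_norm_mean",
    "pwd20", "pwd30", "pwd40", "pwd50", "pwd70", "pwd80", "pwd90",
    "pwd20cF", "pwd30cF", "pwd40cF", "pwd50cF", "pwd70cF", "pwd80cF", "pwd90cF",
    "pwd30_80", "pwd30_80_uncorrected", "plateau_ratio", "ibi_cv",
    "window_start_s", "window_end_s", "event_label",
]

DOSE_RESPONSE_COLUMNS = ["drug", "group", "concentration_uM", "parameter", "mean_pct", "sd_pct", "n"]
INCIDENCE_COLUMNS = ["drug", "group", "concentration_uM", "n", "n_irregular", "n_ead", "n_arrest"]
STATS_COLUMNS = ["comparison", "test", "shapiro_p_a", "shapiro_p_b", "variance_p",
                 "statistic", "p", "sig05", "sig01"]


def _ordered(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame(columns=columns)
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan
    return df[columns]


def write_results(summaries: pd.DataFrame, dose_response: pd.DataFrame,
                  incidence: pd.DataFrame, out_dir: str | os.PathLike,
                  stats: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the per-well summary, dose-response, incidence (and stats) tables.

    Column order is fixed and documented; durations are milliseconds with
    3 decimal places.  Empty inputs produce header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ws = _ordered(summaries.copy() if summaries is not None else None, WELL_SUMMARY_COLUMNS)
    float_cols = [c for c in WELL_SUMMARY_COLUMNS if c.startswith(("pwd", "plateau", "beat",
                                                                  "amplitude", "v_", "ibi", "window"))]
    ws[float_cols] = ws[float_cols].astype(float).round(3)
    paths["well_summary"] = out / "well_summary.csv"
    ws.to_csv(paths["well_summary"], index=False)

    dr = _ordered(dose_response.copy() if dose_response is not None else None, DOSE_RESPONSE_COLUMNS)
    paths["dose_response"] = out / "dose_response.csv"
    dr.to_csv(paths["dose_response"], index=False)

    inc = _ordered(incidence.copy() if incidence is not None else None, INCIDENCE_COLUMNS)
    paths["incidence"] = out / "incidence.csv"
    inc.to_csv(paths["incidence"], index=False)

    if stats is not None:
        st = _ordered(stats.copy(), STATS_COLUMNS)
        paths["stats"] = out / "stats.csv"
        st.to_csv(paths["stats"], index=False)
    return paths
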