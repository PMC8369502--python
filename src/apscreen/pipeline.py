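"""End-to-end plate analysis: traces in, results tables out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import Beat, WellSummary, analyze_trace
from .events import DEFAULT_THRESHOLDS, ClassifierThresholds, EventCall, classify_well, incidence_table
from .io import PlateRecording, read_plate, write_results
from .stats import build_dose_response, group_comparison_table, per_well_percent_changes


@dataclass
class PlateAnalysis:
    """All per-well and per-condition outputs of one analyzed plate."""

    summaries: pd.DataFrame                 # one row per (well, phase)
    calls: list[EventCall]                  # post-phase event labels
    incidence: pd.DataFrame
    dose_response: pd.DataFrame
    stats: pd.DataFrame
    beats: dict[tuple[str, str], list[Beat]] = field(default_factory=dict)
    well_summaries: dict[tuple[str, str], WellSummary] = field(default_factory=dict)


def analyze_plate(rec: PlateRecording, window_s: float = 30.0,
                  thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> PlateAnalysis:
    """Run the full pipeline on a paired pre/post plate recording.

    Every trace is detrended, beat-detected, measured and summarized over the
    first ``window_s`` seconds; post-compound recordings are additionally
    classified as normal / irregular / EAD / arrest.  Percent-change
    dose-response tables and CT-vs-AM comparisons are built from the paired
    summaries.
    """
    rows = []
    calls: list[EventCall] = []
    beats_by_key: dict[tuple[str, str], list[Beat]] = {}
    sums_by_key: dict[tuple[str, str], WellSummary] = {}
    meta_rows = []
    for well in rec.well_ids():
        for phase, trace in sorted(rec.wells[well].items()):
            det, beats, summary = analyze_trace(trace, window_s=window_s)
            beats_by_key[(well, phase)] = beats
            sums_by_key[(well, phase)] = summary
            row = summary.to_row()
            row.update({
                "phase": phase, "group": trace.group, "drug": trace.drug or "none",
                "concentration_uM": trace.concentration, "event_label": "",
            })
            if phase == "post":
                call = classify_well(det, beats, summary, thresholds)
                calls.append(call)
                row["event_label"] = call.label
                meta_rows.append({
                    "well": well, "group": trace.group, "drug": trace.drug or "none",
                    "concentration_uM": trace.concentration,
                })
            rows.append(row)
    summaries = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows, columns=["well", "group", "drug", "concentration_uM"])
    incidence = (incidence_table(calls, meta) if calls
                 else pd.DataFrame(columns=["drug", "group", "concentration_uM", "n",
                                            "n_irregular", "n_ead", "n_arrest"]))
    if {"pre", "post"} <= set(summaries.get("phase", pd.Series(dtype=str))):
        per_well = per_well_percent_changes(summaries)
        dose_response = build_dose_response(summaries)
        stats = group_comparison_table(per_well)
    else:
        dose_response = pd.DataFrame(columns=["drug", "group", "concentration_uM",
                                              "parameter", "mean_pct", "sd_pct", "n"])
        stats = pd.DataFrame()
    return PlateAnalysis(summaries=summaries, calls=calls, incidence=incidence,
                         dose_response=dose_response, stats=stats,
                         beats=beats_by_key, well_summaries=sums_by_key)


def run_analysis(trace_csvs, plate_map_path, out_dir: str | Path,
                 window_s: float = 30.0,
                 thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> PlateAnalysis:
    """File-level entry point: read a plate, analyze it, write the result CSVs."""
    rec = read_plate(trace_csvs, plate_map_path)
    analysis = analyze_plate(rec, window_s=window_s, thresholds=thresholds)
    write_results(analysis.summaries, analysis.dose_response, analysis.incidence,
                  out_dir, stats=analysis.stats)
    return analysis
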