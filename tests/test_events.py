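"""Arrhythmia-like event detectors and the well classifier."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import apscreen as ap
from apscreen.beats import WellSummary, analyze_trace
from apscreen.events import (
    DEFAULT_THRESHOLDS,
    classify_well,
    detect_arrest,
    detect_ead,
    detect_irregular,
    incidence_table,
)


def _analyze(preset, seed, event=None, duration=30.0):
    tr, gt = ap.generate_trace(preset, duration, 5.0, seed=seed,
                               event=event or ap.EventSpec())
    det, beats, s = analyze_trace(tr, window_s=duration)
    return det, beats, s, gt


class TestDetectEad:
    def test_injected_bump_flagged(self, ct_clean):
        ev = ap.EventSpec(kind="ead", bump_frac=0.10, phase_frac=0.5, beat_frac=1.0)
        det, beats, s, gt = _analyze(replace(ct_clean, noise_sd=0.01), 3, ev)
        flags, prom = detect_ead(det, beats)
        assert sum(flags) >= 0.8 * len(beats)
        assert prom >= 0.05

    def test_clean_beat_not_flagged(self, ct_clean):
        det, beats, s, gt = _analyze(ct_clean, 3)
        flags, prom = detect_ead(det, beats)
        assert not any(flags)
        assert prom < 0.05

    def test_false_positive_beat_rate_under_noise(self):
        """No injection, noise 2% of amplitude, 12 wells: beat-level FP < 1%."""
        preset = replace(ap.CT_PRESET, noise_sd=0.02)
        n_beats = n_fp = 0
        for seed in range(12):
            det, beats, s, gt = _analyze(preset, 300 + seed)
            flags, _ = detect_ead(det, beats)
            n_beats += len(flags)
            n_fp += sum(flags)
        assert n_beats > 400
        assert n_fp / n_beats < 0.01


class TestDetectIrregular:
    def test_constant_ibis_not_flagged(self, am_trace_analyzed):
        _, _, _, beats, _ = am_trace_analyzed
        flag, cv = detect_irregular(beats)
        assert flag is False
        assert cv < 0.05

    def test_injected_irregular_flagged(self):
        ev = ap.EventSpec(kind="irregular", cv=0.30)
        det, beats, s, gt = _analyze(ap.AM_PRESET, 5, ev)
        flag, cv = detect_irregular(beats)
        assert flag is True
        assert cv > DEFAULT_THRESHOLDS.irregular_cv_threshold

    def test_too_few_beats_not_evaluable(self, am_trace_analyzed):
        _, _, _, beats, _ = am_trace_analyzed
        flag, cv = detect_irregular(beats[:3])
        assert flag is None
        assert np.isnan(cv)


class TestDetectArrest:
    def test_arrest_injection_flagged(self):
        ev = ap.EventSpec(kind="arrest", onset_s=0.0)
        det, beats, s, gt = _analyze(ap.CT_PRESET, 6, ev)
        assert detect_arrest(s) is True

    def test_normal_am_trace_not_flagged(self, am_trace_analyzed):
        _, _, _, _, s = am_trace_analyzed
        assert s.n_beats > 100  # ~118 beats per 30 s
        assert detect_arrest(s) is False

    def test_two_beats_is_boundary_not_arrest(self):
        s = WellSummary(well_id="w", n_beats=2, window=(0.0, 30.0))
        assert detect_arrest(s) is False
        s1 = WellSummary(well_id="w", n_beats=1, window=(0.0, 30.0))
        assert detect_arrest(s1) is True


class TestClassifyWell:
    def test_priority_arrest_over_ead(self):
        """A well that stops beating is arrest even if it also had EAD-like beats."""
        ev = ap.EventSpec(kind="arrest", onset_s=0.0)
        det, beats, s, gt = _analyze(ap.CT_PRESET, 7, ev)
        call = classify_well(det, beats, s)
        assert call.label == "arrest"

    def test_ead_label_requires_flagged_beats(self, ct_clean):
        ev = ap.EventSpec(kind="ead", bump_frac=0.10, phase_frac=0.5, beat_frac=1.0)
        det, beats, s, gt = _analyze(replace(ct_clean, noise_sd=0.01), 8, ev)
        call = classify_well(det, beats, s)
        assert call.label == "EAD"
        assert call.n_ead_beats >= 1

    def test_normal_well(self, ct_trace_analyzed):
        _, _, det, beats, s = ct_trace_analyzed
        call = classify_well(det, beats, s)
        assert call.label == "normal"


class TestIncidenceTable:
    def _calls(self, labels):
        from apscreen.events import EventCall
        return [EventCall(well_id=f"A{i+1}", label=lab) for i, lab in enumerate(labels)]

    def _meta(self, n, drug="d", group="CT", conc=10.0):
        return pd.DataFrame({
            "well": [f"A{i+1}" for i in range(n)], "group": [group] * n,
            "drug": [drug] * n, "concentration_uM": [conc] * n,
        })

    def test_counts_and_denominator(self):
        table = incidence_table(
            self._calls(["EAD", "EAD", "arrest", "arrest", "arrest", "arrest"]),
            self._meta(6))
        row = table.iloc[0]
        assert (row["n"], row["n_ead"], row["n_arrest"], row["n_irregular"]) == (6, 2, 4, 0)

    def test_all_normal_plate(self):
        table = incidence_table(self._calls(["normal"] * 9), self._meta(9))
        row = table.iloc[0]
        assert row["n"] == 9
        assert row[["n_irregular", "n_ead", "n_arrest"]].sum() == 0

    def test_row_order_deterministic(self):
        calls = self._calls(["normal"] * 4)
        meta = pd.concat([
            self._meta(2, drug="b", conc=10.0),
            self._meta(2, drug="a", conc=1.0).assign(well=["A3", "A4"]),
        ])
        table = incidence_table(calls, meta)
        assert list(table["drug"]) == ["a", "b"]

    def test_labels_exhaustive_and_exclusive(self):
        """Every analyzed well gets exactly one label; denominators add up."""
        sim = ap.generate_plate(ap.condition_fixture("donepezil_ct_10um"))
        from conftest import recording_from_sim
        ana = ap.analyze_plate(recording_from_sim(sim))
        assert len(ana.calls) == 6
        row = ana.incidence.iloc[0]
        assert row["n"] == 6
        labeled = row[["n_irregular", "n_ead", "n_arrest"]].sum()
        n_normal = sum(1 for c in ana.calls if c.label == "normal")
        assert labeled + n_normal == 6
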