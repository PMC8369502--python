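"""Trace generation, event injection, and plate assembly."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import apscreen as ap
from apscreen._errors import InvalidConfigError
from apscreen.beats import detect_beats, detrend


class TestGenerateTrace:
    def test_beat_count_matches_rate(self, ct_trace_analyzed):
        _, gt, _, _, _ = ct_trace_analyzed
        expected = math.floor(30 * 83.7 / 60)  # 41
        assert abs(gt.n_beats - expected) <= 1

    def test_determinism_bitwise(self):
        a, _ = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=11)
        b, _ = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=11)
        assert np.array_equal(a.signal, b.signal)
        c, _ = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=12)
        assert not np.array_equal(a.signal, c.signal)

    def test_noiseless_trace_is_periodic(self):
        # rate 80/min -> period 0.75 s = exactly 150 samples at 5 ms
        preset = ap.PhenotypePreset.from_corrected(
            "P", 80.0,
            {0.2: 100.0, 0.3: 120.0, 0.4: 140.0, 0.5: 160.0,
             0.7: 200.0, 0.8: 230.0, 0.9: 260.0},
            noise_sd=0.0, drift_rate=0.0, rate_jitter_cv=0.0)
        trace, _ = ap.generate_trace(preset, 10.0, 5.0, seed=3)
        n_per = 150
        interior = np.abs(trace.signal[n_per:-300] - trace.signal[:-n_per - 300])
        assert interior.max() < 1e-9

    def test_noise_scaling(self):
        preset = replace(ap.CT_PRESET, drift_rate=0.0)
        noisy, _ = ap.generate_trace(preset, 30.0, 5.0, seed=5)
        clean, _ = ap.generate_trace(replace(preset, noise_sd=0.0), 30.0, 5.0, seed=5)
        resid = noisy.signal - clean.signal
        assert resid.std() == pytest.approx(preset.noise_sd * preset.amplitude, rel=0.10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ap.generate_trace(ap.CT_PRESET, duration=-1.0)
        with pytest.raises(ValueError):
            ap.generate_trace(ap.CT_PRESET, sampling_interval=0.0)

    def test_ground_truth_records_onsets(self, am_trace_analyzed):
        _, gt, _, _, _ = am_trace_analyzed
        assert len(gt.activation_times) == gt.n_beats
        assert np.all(np.diff(gt.activation_times) > 0)


class TestInjectEvent:
    def test_arrest_at_zero_removes_all_beats(self):
        tr, gt = ap.generate_trace(ap.CT_PRESET, 30.0, 5.0, seed=12)
        tra, gta = ap.inject_event(tr, gt, ap.EventSpec(kind="arrest", onset_s=0.0))
        assert gta.n_beats == 0
        assert detect_beats(detrend(tra)) == []

    def test_arrest_beyond_trace_end_rejected(self):
        tr, gt = ap.generate_trace(ap.CT_PRESET, 30.0, 5.0, seed=12)
        with pytest.raises(ValueError):
            ap.inject_event(tr, gt, ap.EventSpec(kind="arrest", onset_s=60.0))

    def test_arrest_preserves_baseline_and_noise(self):
        tr, gt = ap.generate_trace(ap.CT_PRESET, 30.0, 5.0, seed=12)
        tra, _ = ap.inject_event(tr, gt, ap.EventSpec(kind="arrest", onset_s=0.0))
        # samples before the first beat's support (which starts 40 ms in)
        # are bitwise unchanged
        n = int(0.035 / tr.dt_s)
        assert np.array_equal(tr.signal[:n], tra.signal[:n])

    def test_irregular_cv_zero_is_identity(self):
        tr, gt = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=13)
        tri, _ = ap.inject_event(tr, gt, ap.EventSpec(kind="irregular", cv=0.0))
        assert np.array_equal(tr.signal, tri.signal)

    def test_irregular_raises_realized_ibi_cv(self):
        tr, gt = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=13)
        _, gti = ap.inject_event(tr, gt, ap.EventSpec(kind="irregular", cv=0.30))
        assert gti.ibi_cv > 0.20
        assert gt.ibi_cv < 0.05

    def test_ead_creates_local_maximum_on_every_beat(self, ct_clean):
        ev = ap.EventSpec(kind="ead", bump_frac=0.10, phase_frac=0.5, beat_frac=1.0)
        tr, gt = ap.generate_trace(ct_clean, 10.0, 5.0, seed=1, event=ev)
        y = tr.signal
        dy = np.diff(y)
        for a in gt.activation_times:
            # the limb must rise (dy > 0) and then fall again: a local maximum
            i0 = int((a + 0.05) / tr.dt_s)
            i1 = int((a + gt.apd_true[0.9] / 1000.0) / tr.dt_s)
            seg = dy[i0:i1]
            local_max = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0))
            assert local_max.size >= 1

    def test_ead_params_validated(self):
        with pytest.raises(InvalidConfigError):
            ap.EventSpec(kind="ead", bump_frac=1.5)
        with pytest.raises(InvalidConfigError):
            ap.EventSpec(kind="ead", phase_frac=0.95)


class TestGeneratePlate:
    def test_plate_shape(self):
        wells = [ap.WellSpec(well=f"A{i}", group="CT", phase="post", seed=i)
                 for i in range(1, 7)]
        sim = ap.generate_plate(ap.PlateConfig(wells=wells))
        frame = sim.trace_frames["post"]
        assert list(frame.columns) == ["time_s"] + [f"A{i}" for i in range(1, 7)]

    def test_duplicate_wells_rejected(self):
        wells = [ap.WellSpec(well="A1", group="CT", phase="post", seed=1)] * 2
        with pytest.raises(InvalidConfigError):
            ap.generate_plate(ap.PlateConfig(wells=wells))

    def test_empty_config_yields_time_only_csv(self):
        sim = ap.generate_plate(ap.PlateConfig(wells=[]))
        frame = next(iter(sim.trace_frames.values()))
        assert list(frame.columns) == ["time_s"]
        assert len(frame) > 0

    def test_donepezil_fixture_ground_truth_counts(self):
        sim = ap.generate_plate(ap.condition_fixture("donepezil_ct_10um"))
        gt = sim.ground_truth_frame
        post = gt[gt["phase"] == "post"]
        assert (post["event"] == "ead").sum() == 2
        assert (post["event"] == "arrest").sum() == 4

    def test_drug_model_applied_to_post_phase_only(self):
        drug = ap.DrugEffectModel("dx", effects=(
            ap.DrugEffect(target="beat_rate", direction="decrease",
                          emax=0.5, ec50=1.0, hill_coefficient=1.0),))
        wells = [
            ap.WellSpec(well="A1", group="CT", phase="pre", drug="dx",
                        concentration=100.0, seed=1),
            ap.WellSpec(well="A1", group="CT", phase="post", drug="dx",
                        concentration=100.0, seed=1),
        ]
        sim = ap.generate_plate(ap.PlateConfig(wells=wells, drugs={"dx": drug}))
        rate_pre = sim.ground_truth[("A1", "pre")].rate_true
        rate_post = sim.ground_truth[("A1", "post")].rate_true
        assert rate_pre == pytest.approx(83.7)
        assert rate_post == pytest.approx(83.7 * (1 - 0.5 * 100 / 101), rel=1e-6)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_text = """
duration_s: 10
sampling_interval_ms: 5
wells:
  - {well: A1, group: CT, phase: post, seed: 1, event: arrest, onset_s: 0}
  - {well: A2, group: AM, phase: post, seed: 2}
"""
        p = tmp_path / "cfg.yaml"
        p.write_text(cfg_text)
        cfg = ap.load_plate_config(p)
        assert cfg.duration_s == 10
        assert cfg.wells[0].event.kind == "arrest"
        sim = ap.generate_plate(cfg)
        assert set(sim.trace_frames["post"].columns) == {"time_s", "A1", "A2"}
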