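"""Beat detection and waveform measurement against analytic and ground-truth oracles."""

from dataclasses import replace

import numpy as np
import pytest

import apscreen as ap
from apscreen.beats import (
    detect_beats,
    detrend,
    fridericia_correct,
    plateau_ratio,
    summarize_well,
)
from apscreen.io import Trace


class TestTriangleBeatOracle:
    """Instantaneous upstroke + linear 100-ms decay: every duration is analytic."""

    def test_pwd_values(self, triangle_trace):
        trace, _ = triangle_trace
        (beat,) = detect_beats(trace)
        for frac in (0.20, 0.30, 0.40, 0.50, 0.70, 0.80):
            assert beat.pwd[frac] == pytest.approx(frac * 100.0, abs=0.1)

    def test_falling_slope(self, triangle_trace):
        trace, amplitude = triangle_trace
        (beat,) = detect_beats(trace)
        assert beat.v_down_max == pytest.approx(amplitude / 0.1, rel=1e-6)
        assert beat.amplitude == pytest.approx(amplitude, rel=1e-6)

    def test_plateau_ratio_of_linear_decay_is_one(self, triangle_trace):
        trace, _ = triangle_trace
        (beat,) = detect_beats(trace)
        # equal 10-percentage-point widths: (PWD40-PWD30)/(PWD80-PWD70) = 1
        assert plateau_ratio(beat) == pytest.approx(1.0, abs=0.01)


class TestFridericia:
    def test_identity_at_one_second(self):
        assert fridericia_correct(300.0, 1.0) == pytest.approx(300.0, abs=1e-12)

    def test_direct_evaluation(self):
        assert fridericia_correct(200.0, 0.5) == pytest.approx(200.0 / 0.5 ** (1 / 3), rel=1e-12)
        assert fridericia_correct(200.0, 0.5) == pytest.approx(252.0, abs=0.1)

    def test_invalid_ibi(self):
        with pytest.raises(ValueError):
            fridericia_correct(200.0, 0.0)


class TestDetrend:
    def test_drifting_beat_free_trace_flattened(self):
        # -10%/min linear drift, no beats
        t = np.arange(0, 30, 0.005)
        y = 10.0 - (0.10 * 1.0 / 60.0) * t
        trace = Trace(well_id="d", time=t, signal=y, sampling_interval=5.0)
        out = detrend(trace)
        slope_in = np.polyfit(t, y, 1)[0]
        slope_out = np.polyfit(t, out.signal, 1)[0]
        assert abs(slope_out) < 0.01 * abs(slope_in)

    def test_zero_drift_noiseless_trace_shifted_by_constant(self, ct_clean):
        trace, _ = ap.generate_trace(ct_clean, 30.0, 5.0, seed=4)
        out = detrend(trace)
        resid = trace.signal - out.signal
        assert resid.std() < 0.02 * ct_clean.amplitude  # constant offset only

    def test_amplitudes_preserved_under_drift(self):
        preset = replace(ap.CT_PRESET, noise_sd=0.0, rate_jitter_cv=0.0, drift_rate=0.10)
        trace, gt = ap.generate_trace(preset, 30.0, 5.0, seed=4)
        _, beats, _ = ap.analyze_trace(trace)
        drift_factor = 1.0 - preset.drift_rate * np.array([b.t_activation for b in beats]) / 60.0
        expected = gt.amplitude_true * drift_factor
        got = np.array([b.amplitude for b in beats])
        np.testing.assert_allclose(got, expected, rtol=0.02)

    def test_short_trace_passes_through(self, ct_clean):
        t = np.arange(0, 0.5, 0.005)
        y = np.ones_like(t)
        trace = Trace(well_id="s", time=t, signal=y, sampling_interval=5.0)
        out = detrend(trace)
        np.testing.assert_array_equal(out.signal, y)


class TestDetectBeats:
    def test_noiseless_count_matches_ground_truth(self, ct_clean):
        trace, gt = ap.generate_trace(ct_clean, 30.0, 5.0, seed=7)
        beats = detect_beats(detrend(trace))
        assert len(beats) == gt.n_beats

    def test_flat_noise_only_trace_yields_no_beats(self):
        tr, gt = ap.generate_trace(ap.CT_PRESET, 30.0, 5.0, seed=21,
                                   event=ap.EventSpec(kind="arrest", onset_s=0.0))
        assert detect_beats(detrend(tr)) == []

    def test_am_activation_times_within_two_samples(self):
        preset = replace(ap.AM_PRESET, noise_sd=0.05)
        trace, gt = ap.generate_trace(preset, 30.0, 5.0, seed=9)
        beats = detect_beats(detrend(trace))
        assert len(beats) == gt.n_beats
        err = np.abs(np.array([b.t_activation for b in beats]) - gt.activation_times)
        assert np.max(err) <= 2 * trace.dt_s

    def test_pwd_monotone_on_every_beat(self, ct_trace_analyzed, am_trace_analyzed):
        for _, _, _, beats, _ in (ct_trace_analyzed, am_trace_analyzed):
            for b in beats:
                vals = [b.pwd[f] for f in ap.FRACTIONS if b.pwd.get(f) is not None]
                assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_sampling_robustness_5_vs_10_ms(self, ct_clean):
        t5, _ = ap.generate_trace(ct_clean, 30.0, 5.0, seed=7)
        t10, _ = ap.generate_trace(ct_clean, 30.0, 10.0, seed=7)
        _, _, s5 = ap.analyze_trace(t5)
        _, _, s10 = ap.analyze_trace(t10)
        for f in ap.FRACTIONS:
            assert s10.pwd[f] == pytest.approx(s5.pwd[f], abs=10.0)


class TestSummarizeWell:
    def test_noise_free_summary_matches_ground_truth(self, am_clean):
        trace, gt = ap.generate_trace(am_clean, 30.0, 5.0, seed=7)
        _, _, s = ap.analyze_trace(trace)
        assert s.beat_rate == pytest.approx(gt.rate_true, abs=1.0)
        assert s.amplitude_mean == pytest.approx(gt.amplitude_true, rel=0.02)
        assert s.v_up_mean == pytest.approx(gt.v_up_true, rel=0.02)
        assert s.v_down_mean == pytest.approx(gt.v_down_true, rel=0.02)
        for f, target in gt.apd_true.items():
            assert s.pwd[f] == pytest.approx(target, abs=1.0)

    def test_apd90_bias_under_noise_below_3ms(self):
        preset = replace(ap.CT_PRESET, noise_sd=0.05)
        errs = []
        for seed in range(12):
            trace, gt = ap.generate_trace(preset, 30.0, 5.0, seed=100 + seed)
            _, _, s = ap.analyze_trace(trace)
            errs.append(s.pwd[0.90] - gt.apd_true[0.90])
        assert abs(np.mean(errs)) < 3.0

    def test_pwd30_80_identity(self, ct_trace_analyzed):
        _, _, _, _, s = ct_trace_analyzed
        assert s.pwd30_80_uncorrected == pytest.approx(s.pwd[0.80] - s.pwd[0.30], abs=1e-6)
        assert s.pwd30_80 == pytest.approx(s.pwd_cf[0.80] - s.pwd_cf[0.30], abs=1e-6)

    def test_single_beat_window(self, ct_trace_analyzed):
        _, _, _, beats, _ = ct_trace_analyzed
        b0 = beats[0]
        s = summarize_well([b0], window=(0.0, 30.0), well_id="w")
        assert np.isnan(s.beat_rate)
        assert s.n_beats == 1
        assert s.pwd[0.50] == pytest.approx(b0.pwd[0.50])

    def test_empty_window_gives_arrest_candidate(self):
        s = summarize_well([], window=(0.0, 30.0), well_id="w")
        assert s.n_beats == 0
        assert np.isnan(s.beat_rate)
        assert all(np.isnan(v) for v in s.pwd.values()) or not s.pwd

    def test_beat_rate_consistent_with_count(self, am_trace_analyzed):
        _, _, _, _, s = am_trace_analyzed
        # (n-1)/span*60 agrees with n scaled to the window within one beat
        assert s.beat_rate == pytest.approx(s.n_beats * 2.0, abs=2.5)
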