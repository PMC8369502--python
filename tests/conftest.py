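"""Shared fixtures: calibrated presets and reference traces are session-scoped
because calibration and 30-s trace analysis dominate the suite's runtime."""

from dataclasses import replace

import numpy as np
import pytest

import apscreen as ap


@pytest.fixture(scope="session")
def ct_clean():
    return replace(ap.CT_PRESET, noise_sd=0.0, drift_rate=0.0, rate_jitter_cv=0.0)


@pytest.fixture(scope="session")
def am_clean():
    return replace(ap.AM_PRESET, noise_sd=0.0, drift_rate=0.0, rate_jitter_cv=0.0)


@pytest.fixture(scope="session")
def ct_trace_analyzed():
    """CT default-preset 30-s trace (seed 42) through the full pipeline."""
    trace, gt = ap.generate_trace(ap.CT_PRESET, 30.0, 5.0, seed=42)
    det, beats, summary = ap.analyze_trace(trace)
    return trace, gt, det, beats, summary


@pytest.fixture(scope="session")
def am_trace_analyzed():
    """AM default-preset 30-s trace (seed 42) through the full pipeline."""
    trace, gt = ap.generate_trace(ap.AM_PRESET, 30.0, 5.0, seed=42)
    det, beats, summary = ap.analyze_trace(trace)
    return trace, gt, det, beats, summary


@pytest.fixture(scope="session")
def triangle_trace():
    """Idealized beat: instantaneous upstroke to A at t = 0, linear decay to
    baseline over 100 ms, 1-ms sampling — all durations analytic."""
    amplitude = 2.0
    t = np.arange(-0.2, 0.3, 0.001)
    y = np.where(t < 0, 0.0, np.where(t <= 0.1, amplitude * (1 - t / 0.1), 0.0))
    return ap.Trace(well_id="tri", time=t, signal=y, sampling_interval=1.0), amplitude


def recording_from_sim(sim):
    """Assemble a PlateRecording from an in-memory PlateSim."""
    wells = {}
    for phase, traces in sim.traces.items():
        for well, tr in traces.items():
            wells.setdefault(well, {})[phase] = tr
    return ap.PlateRecording(wells=wells)
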