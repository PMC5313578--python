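"""Breath detection and windowed rate/depth estimators against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from expotrack.airflow_metrics import (
    AirflowSeries,
    BreathEvent,
    airflow_depth,
    airflow_rate,
    breath_metrics,
    detect_breaths,
)
from expotrack.errors import InsufficientDataError, ParameterError

FS = 10.0


def sine_series(period_s, duration_s, amplitude=1.0, offset=0.0, noise_sd=0.0, seed=0):
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    v = amplitude * np.sin(2 * np.pi * t / period_s) + offset
    if noise_sd:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, n)
    return AirflowSeries(t, v, FS)


def upward_zero_crossings(values):
    """Independent oracle: one breath cycle per upward zero crossing.

    The pre-start state counts as negative, so a cycle beginning exactly
    at t = 0 (sin rising from zero) is included.
    """
    s = np.concatenate([[True], values < 0])
    return int(np.sum(s[:-1] & ~s[1:]))


def test_event_count_matches_zero_crossing_oracle():
    series = sine_series(period_s=4.0, duration_s=60.0)
    oracle = upward_zero_crossings(series.values)
    events = detect_breaths(series, min_prominence=0.5)
    assert len(events) == oracle == 15


def test_constant_signal_has_no_breaths():
    series = AirflowSeries(np.arange(100) / FS, np.full(100, 3.3), FS)
    assert detect_breaths(series) == []


def test_noisy_sine_count_within_one_of_truth():
    # SNR 10 in amplitude: sigma = amplitude / 10
    series = sine_series(period_s=4.0, duration_s=120.0, noise_sd=0.1, seed=42)
    events = detect_breaths(series)
    assert abs(len(events) - 30) <= 1


def test_events_ordered_and_well_formed():
    series = sine_series(period_s=3.0, duration_s=30.0)
    events = detect_breaths(series)
    for e in events:
        assert e.t_start <= e.t_peak <= e.t_end
        assert e.amplitude > 0
    for a, b in zip(events, events[1:]):
        assert a.t_end <= b.t_start or a.t_peak < b.t_peak  # time-ordered, non-overlapping


def test_metrics_invariant_to_constant_offset():
    base = sine_series(period_s=4.0, duration_s=120.0)
    shifted = AirflowSeries(base.timestamps, base.values + 250.0, FS)
    grid = np.arange(0, 120.0)
    m0 = breath_metrics(base, grid)
    m1 = breath_metrics(shifted, grid)
    np.testing.assert_allclose(m0.airflow_rate, m1.airflow_rate)
    np.testing.assert_allclose(m0.airflow_depth, m1.airflow_depth, atol=1e-9)


@given(st.floats(0.01, 100.0))
def test_scaling_scales_depth_and_leaves_rate(k):
    base = sine_series(period_s=4.0, duration_s=60.0)
    scaled = AirflowSeries(base.timestamps, base.values * k, FS)
    grid = np.arange(0, 60.0)
    m0 = breath_metrics(base, grid)
    m1 = breath_metrics(scaled, grid)
    np.testing.assert_allclose(m0.airflow_rate, m1.airflow_rate)
    np.testing.assert_allclose(m1.airflow_depth, k * m0.airflow_depth, rtol=1e-9)


def events_every(period_s, t0, t1, amplitude=2.0):
    peaks = np.arange(t0, t1, period_s)
    return [BreathEvent(p - 0.5, p, p + 0.5, amplitude) for p in peaks]


def test_rate_direct_count_oracle():
    events = events_every(4.0, 0.0, 120.0)
    grid = np.arange(0, 120.0)
    rate = airflow_rate(events, grid, window_s=30.0)
    # interior: 30 s windows hold 7 or 8 of the 4 s-spaced peaks -> 14-16/min, mean 15
    interior = rate[40:]
    assert np.all((interior >= 14.0) & (interior <= 16.0))
    assert np.mean(interior) == pytest.approx(15.0, rel=0.02)
    # oracle per grid point
    peaks = np.array([e.t_peak for e in events])
    for t in (50.0, 80.0, 110.0):
        n = np.sum((peaks > t - 30.0) & (peaks <= t))
        assert rate[int(t)] == pytest.approx(60.0 * n / 30.0)


def test_rate_no_events_is_zero():
    assert np.all(airflow_rate([], np.arange(10.0), 30.0) == 0.0)


def test_rate_rises_across_transition_and_matches_sliding_count_oracle():
    events = events_every(5.0, 0.0, 60.0) + events_every(2.0, 60.0, 120.0)
    grid = np.arange(0, 120.0)
    rate = airflow_rate(events, grid, window_s=30.0)
    # sliding-count oracle, point by point
    peaks = np.array([e.t_peak for e in events])
    oracle = np.array([np.sum((peaks > t - 30.0) & (peaks <= t)) * 2.0 for t in grid])
    np.testing.assert_array_equal(rate, oracle)
    # rises monotonically at the 5 s-block scale (single counts jitter by +-1 event)
    blocks = rate[55:95].reshape(8, 5).mean(axis=1)
    assert np.all(np.diff(blocks) >= 0.0)
    assert rate[59] == pytest.approx(12.0, abs=2.1)
    assert rate[119] == pytest.approx(30.0, abs=2.1)


def test_depth_is_windowed_mean_of_amplitudes():
    events = events_every(4.0, 0.0, 120.0, amplitude=2.0)
    grid = np.arange(0, 120.0)
    depth = airflow_depth(events, grid, window_s=30.0)
    assert np.all(depth[35:] == 2.0)
    assert np.all(airflow_depth([], grid, 30.0) == 0.0)


def test_depth_nondecreasing_for_ramping_amplitudes():
    peaks = np.arange(2.0, 120.0, 4.0)
    amps = np.linspace(1.0, 3.0, peaks.size)
    events = [BreathEvent(p - 1, p, p + 1, a) for p, a in zip(peaks, amps)]
    grid = np.arange(0, 120.0)
    depth = airflow_depth(events, grid, window_s=30.0)
    assert np.all(np.diff(depth[2:]) >= -1e-12)
    # window-mean oracle at a grid point
    t = 80.0
    m = (peaks > t - 30.0) & (peaks <= t)
    assert depth[80] == pytest.approx(amps[m].mean())


@pytest.mark.parametrize("bpm", [10, 15, 25])
def test_steady_state_rate_recovery_within_ten_percent(bpm):
    series = sine_series(period_s=60.0 / bpm, duration_s=240.0)
    m = breath_metrics(series, np.arange(0, 240.0))
    steady = m.airflow_rate[60:]
    assert abs(steady.mean() - bpm) / bpm < 0.10


def test_too_short_series_raises():
    with pytest.raises(InsufficientDataError):
        detect_breaths(AirflowSeries(np.array([0.0, 0.1]), np.array([0.0, 1.0]), FS))


def test_bad_parameters_raise():
    series = sine_series(4.0, 30.0)
    with pytest.raises(ParameterError):
        detect_breaths(series, min_period_s=0.0)
    with pytest.raises(ParameterError):
        airflow_rate([], np.arange(10.0), window_s=0.0)
    with pytest.raises(ParameterError):
        airflow_depth([], np.arange(10.0), window_s=-1.0)
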