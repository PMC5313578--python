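"""Breathing frequency and relative depth from a nasal-airflow thermocouple signal.

The sensor is a thermocouple resistor worn at the nostrils whose reading
rises with each exhalation, so each breath appears as one peak in the raw
trace.  The trace is first detrended with a zero-phase high-pass filter
(thermocouple drift is much slower than a breath, so a 0.05 Hz cutoff
separates the two cleanly without attenuating even slow breathing),
breaths are detected as prominent peaks with a minimum separation, and
per-second metrics are then formed over a trailing (causal) window:

* **airflow rate** — breaths per minute: 60 x (peaks in the last
  ``window_s`` seconds) / ``window_s``;
* **airflow depth** — mean peak amplitude (raw units above baseline) of
  those breaths.  Depth is relative: the sensor is uncalibrated, so only
  ratios of depth are meaningful.

Both metrics are invariant to a constant offset of the raw signal; scaling
the signal by k > 0 scales depth by k and leaves the rate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import InsufficientDataError, ParameterError

#: trailing window (s) for rate/depth; >= 2x the longest plausible breath period
DEFAULT_WINDOW_S = 30.0
#: shortest plausible breath period (s); ~60 breaths/min ceiling
DEFAULT_MIN_PERIOD_S = 1.0
#: high-pass cutoff (Hz) separating baseline drift from breathing (>= ~6 breaths/min)
BASELINE_CUTOFF_HZ = 0.05
#: low-pass cutoff (Hz) above any plausible breathing rate (72 breaths/min)
BREATH_MAX_HZ = 1.2


@dataclass
class AirflowSeries:
    """A raw airflow trace: strictly increasing timestamps (s) and readings (raw units)."""

    timestamps: np.ndarray
    values: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ParameterError("timestamps and values must have equal length")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BreathEvent:
    """One detected breath cycle; amplitude is the peak height above local baseline."""

    t_start: float
    t_peak: float
    t_end: float
    amplitude: float


@dataclass
class BreathMetricsSeries:
    """Per-second breathing metrics on a common grid."""

    timestamps: np.ndarray
    airflow_rate: np.ndarray  # breaths/min
    airflow_depth: np.ndarray  # raw units above baseline
    window_s: float


def _detrend(values: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Isolate the breathing band with a zero-phase 2nd-order Butterworth filter.

    High-pass at 0.05 Hz removes thermocouple drift; when the sampling
    rate allows, a low-pass at 1.2 Hz also suppresses sensor noise above
    any plausible breathing rate.  Falls back to median subtraction when
    the series is too short to filter.
    """
    nyquist = sample_rate_hz / 2.0
    if BASELINE_CUTOFF_HZ >= nyquist or values.size < 25:
        return values - np.median(values)
    if BREATH_MAX_HZ < 0.9 * nyquist:
        sos = butter(2, [BASELINE_CUTOFF_HZ, BREATH_MAX_HZ], btype="bandpass",
                     fs=sample_rate_hz, output="sos")
    else:
        sos = butter(2, BASELINE_CUTOFF_HZ, btype="highpass",
                     fs=sample_rate_hz, output="sos")
    return sosfiltfilt(sos, values)


def detect_breaths(
    series: AirflowSeries,
    min_prominence: float | None = None,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
) -> list[BreathEvent]:
    """Detect breath cycles as prominent peaks of the baseline-detrended signal.

    ``min_prominence`` is in raw units; when ``None`` an adaptive threshold
    (0.3 x the 95th percentile of the detrended magnitude) is used, which
    makes detection invariant to rescaling of the raw signal.
    """
    if min_period_s <= 0:
        raise ParameterError("min_period_s must be positive")
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 samples to detect breaths")

    span = float(np.ptp(series.values))
    if span == 0.0:
        return []
    detrended = _detrend(series.values, series.sample_rate_hz)
    if min_prominence is None:
        scale = float(np.percentile(np.abs(detrended), 95))
        if scale <= 1e-9 * span:  # filter residue on an effectively flat signal
            return []
        min_prominence = 0.3 * scale
    distance = max(1, int(round(min_period_s * series.sample_rate_hz)))
    peaks, props = find_peaks(detrended, prominence=min_prominence, distance=distance)
    peaks = peaks[detrended[peaks] > 0]
    if peaks.size == 0:
        return []

    t = series.timestamps
    events: list[BreathEvent] = []
    for k, p in enumerate(peaks):
        lo = peaks[k - 1] if k > 0 else 0
        hi = peaks[k + 1] if k + 1 < peaks.size else detrended.size - 1
        i_start = lo + int(np.argmin(detrended[lo : p + 1]))
        i_end = p + int(np.argmin(detrended[p : hi + 1]))
        events.append(
            BreathEvent(
                t_start=float(t[i_start]),
                t_peak=float(t[p]),
                t_end=float(t[i_end]),
                amplitude=float(detrended[p]),
            )
        )
    return events


def _window_slices(peak_times: np.ndarray, grid: np.ndarray, window_s: float):
    """Index ranges of peaks falling in the trailing window (t - window_s, t]."""
    left = np.searchsorted(peak_times, grid - window_s, side="right")
    right = np.searchsorted(peak_times, grid, side="right")
    return left, right


def airflow_rate(
    events: list[BreathEvent], grid: np.ndarray, window_s: float = DEFAULT_WINDOW_S
) -> np.ndarray:
    """Breaths per minute at each grid time, from peak counts in the trailing window."""
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    grid = np.asarray(grid, dtype=float)
    if not events:
        return np.zeros(grid.size)
    peak_times = np.array(sorted(e.t_peak for e in events))
    left, right = _window_slices(peak_times, grid, window_s)
    return 60.0 * (right - left) / window_s


def airflow_depth(
    events: list[BreathEvent], grid: np.ndarray, window_s: float = DEFAULT_WINDOW_S
) -> np.ndarray:
    """Mean breath amplitude over the trailing window; 0 where no breaths fall in it."""
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    grid = np.asarray(grid, dtype=float)
    if not events:
        return np.zeros(grid.size)
    order = np.argsort([e.t_peak for e in events])
    peak_times = np.array([events[i].t_peak for i in order])
    amplitudes = np.array([events[i].amplitude for i in order])
    csum = np.concatenate([[0.0], np.cumsum(amplitudes)])
    left, right = _window_slices(peak_times, grid, window_s)
    count = right - left
    total = csum[right] - csum[left]
    with np.errstate(invalid="ignore"):
        depth = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return depth


def breath_metrics(
    series: AirflowSeries,
    grid: np.ndarray,
    window_s: float = DEFAULT_WINDOW_S,
    min_prominence: float | None = None,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
) -> BreathMetricsSeries:
    """Convenience wrapper: detect breaths, then evaluate rate and depth on ``grid``."""
    events = detect_breaths(series, min_prominence=min_prominence, min_period_s=min_period_s)
    grid = np.asarray(grid, dtype=float)
    return BreathMetricsSeries(
        timestamps=grid,
        airflow_rate=airflow_rate(events, grid, window_s),
        airflow_depth=airflow_depth(events, grid, window_s),
        window_s=window_s,
    )
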