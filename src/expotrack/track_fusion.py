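"""Fuse GPS fixes and sensor-derived channels onto one 1 Hz journey timeline.

The sensors are independent devices with unsynchronised clocks, so fusion
is a nearest-in-time join with a tolerance rather than resampling: each
channel contributes its closest sample within ``max_gap_s`` of a grid
time, and positions are linearly interpolated between bracketing GPS
fixes.  Samples with any missing source are gap-flagged but retained, so
downstream maps show *where* data are missing instead of silently closing
holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EmptyInputError, ParameterError
from .airflow_metrics import BreathMetricsSeries
from .log_io import SensorLog
from .no2_calibration import ConcentrationSeries

DEFAULT_MAX_GAP_S = 3.0


@dataclass
class FusedTrack:
    """All channels of one journey on a common regular grid (epoch seconds)."""

    timestamps: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    no2: np.ndarray
    airflow_rate: np.ndarray
    airflow_depth: np.ndarray
    gap_flags: np.ndarray
    no2_is_relative: bool = False

    def __post_init__(self) -> None:
        n = self.timestamps.size
        for name in ("lat", "lon", "no2", "airflow_rate", "airflow_depth", "gap_flags"):
            arr = np.asarray(getattr(self, name))
            if arr.size != n:
                raise ParameterError(f"{name} length {arr.size} != grid length {n}")
            setattr(self, name, arr)
        self.gap_flags = self.gap_flags.astype(bool)

    def __len__(self) -> int:
        return self.timestamps.size


def build_grid(log: SensorLog, interval_s: float = 1.0) -> np.ndarray:
    """Regular grid (epoch s) spanning the log, anchored at the first timestamp."""
    if interval_s <= 0:
        raise ParameterError("interval_s must be positive")
    if len(log) == 0:
        raise EmptyInputError("cannot build a grid from an empty log")
    t = log.times_s()
    n = int(np.floor((t[-1] - t[0]) / interval_s + 1e-9)) + 1
    return t[0] + np.arange(n) * interval_s


def _nearest_join(
    grid: np.ndarray, times: np.ndarray, values: np.ndarray, max_gap_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closest-sample value per grid time; flag where the gap exceeds the tolerance."""
    idx = np.searchsorted(times, grid)
    idx_lo = np.clip(idx - 1, 0, times.size - 1)
    idx_hi = np.clip(idx, 0, times.size - 1)
    pick = np.where(
        np.abs(grid - times[idx_lo]) <= np.abs(times[idx_hi] - grid), idx_lo, idx_hi
    )
    gap = np.abs(grid - times[pick]) > max_gap_s
    joined = values[pick].astype(float).copy()
    gap |= ~np.isfinite(joined)
    joined[gap] = np.nan
    return joined, gap


def _interp_positions(
    grid: np.ndarray,
    gps_t: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    max_gap_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear lat/lon interpolation between fixes; flag grid times whose bracketing
    fix interval (or distance past the track ends) exceeds ``max_gap_s``."""
    lat_i = np.interp(grid, gps_t, lat)
    lon_i = np.interp(grid, gps_t, lon)
    hi = np.searchsorted(gps_t, grid)
    lo = hi - 1
    gap = np.zeros(grid.size, dtype=bool)
    inside = (lo >= 0) & (hi < gps_t.size)
    exact = inside & (gps_t[np.clip(hi, 0, gps_t.size - 1)] == grid)
    span = np.where(
        inside,
        gps_t[np.clip(hi, 0, gps_t.size - 1)] - gps_t[np.clip(lo, 0, gps_t.size - 1)],
        np.inf,
    )
    gap |= inside & ~exact & (span > max_gap_s)
    gap |= (lo < 0) & (gps_t[0] - grid > max_gap_s)
    gap |= (hi >= gps_t.size) & (grid - gps_t[-1] > max_gap_s)
    lat_i = lat_i.copy()
    lon_i = lon_i.copy()
    lat_i[gap] = np.nan
    lon_i[gap] = np.nan
    return lat_i, lon_i, gap


def align(
    grid: np.ndarray,
    gps: tuple[np.ndarray, np.ndarray, np.ndarray],
    no2_series: ConcentrationSeries,
    breath_metrics: BreathMetricsSeries,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> FusedTrack:
    """Join GPS (times, lat, lon), NO2 and breathing metrics onto ``grid``.

    Raises :class:`AlignmentError` if any stream has no overlap with the
    grid (allowing the gap tolerance at each end).
    """
    grid = np.asarray(grid, dtype=float)
    gps_t, gps_lat, gps_lon = (np.asarray(a, dtype=float) for a in gps)
    if no2_series.timestamps is None or breath_metrics.timestamps is None:
        raise ParameterError("no2 and breath-metric series must carry timestamps")

    for name, times in (
        ("gps", gps_t),
        ("no2", no2_series.timestamps),
        ("breath metrics", breath_metrics.timestamps),
    ):
        if times.size == 0:
            raise AlignmentError(f"{name} stream is empty")
        if times[0] > grid[-1] + max_gap_s or times[-1] < grid[0] - max_gap_s:
            raise AlignmentError(f"{name} stream does not overlap the grid")

    lat, lon, gap_pos = _interp_positions(grid, gps_t, gps_lat, gps_lon, max_gap_s)
    no2, gap_no2 = _nearest_join(grid, no2_series.timestamps, no2_series.no2, max_gap_s)
    rate, gap_rate = _nearest_join(
        grid, breath_metrics.timestamps, breath_metrics.airflow_rate, max_gap_s
    )
    depth, gap_depth = _nearest_join(
        grid, breath_metrics.timestamps, breath_metrics.airflow_depth, max_gap_s
    )
    return FusedTrack(
        timestamps=grid,
        lat=lat,
        lon=lon,
        no2=no2,
        airflow_rate=rate,
        airflow_depth=depth,
        gap_flags=gap_pos | gap_no2 | gap_rate | gap_depth,
        no2_is_relative=no2_series.is_relative,
    )


def align_track(track: FusedTrack, max_gap_s: float = DEFAULT_MAX_GAP_S) -> FusedTrack:
    """Re-align a fused track onto its own grid (idempotence helper)."""
    finite = np.isfinite(track.lat)
    return align(
        track.timestamps,
        (track.timestamps[finite], track.lat[finite], track.lon[finite]),
        ConcentrationSeries(track.no2, timestamps=track.timestamps,
                            is_relative=track.no2_is_relative),
        BreathMetricsSeries(track.timestamps, track.airflow_rate,
                            track.airflow_depth, window_s=0.0),
        max_gap_s=max_gap_s,
    )
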