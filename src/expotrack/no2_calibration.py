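"""Raw NO2 sensor readings -> concentration, calibrated or journey-relative.

The gas sensor is a metal-oxide semiconductor whose resistance changes
with ambient NO2.  Chamber calibration against known dilutions of a
certified gas standard yields (concentration, raw reading) points; the
curve through them is a monotone piecewise-linear interpolant.  Because
such curves drift over time, no parametric form is assumed and each curve
carries a ``fitted_at`` stamp.

For the relative exposure index no calibration is needed at all:
``relative_concentration`` min-max scales a journey's raw readings to
[0, 1], which is invariant to any positive affine response of the sensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .errors import CalibrationError, EmptyInputError, InsufficientDataError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "ConcentrationSeries",
    "fit_calibration",
    "apply_calibration",
    "relative_concentration",
    "read_calibration_csv",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # ppm
    raw_reading: float  # sensor units (resistance-derived)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise CalibrationError("concentration must be non-negative")


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear map raw_reading -> concentration (ppm).

    Extrapolation beyond the terminal points continues the terminal
    segment's slope; results are clamped at 0 ppm.  The sensor's monotone
    sense (raw rising or falling with concentration) is inferred from the
    points.
    """

    points: list[CalibrationPoint]
    fitted_at: datetime = field(default_factory=lambda: datetime.now(timezone.utc))

    def __post_init__(self) -> None:
        pts = sorted(self.points, key=lambda p: p.concentration)
        raw = np.array([p.raw_reading for p in pts])
        conc = np.array([p.concentration for p in pts])
        d = np.diff(raw)
        if np.all(d > 0):
            self._sign = 1.0
        elif np.all(d < 0):
            self._sign = -1.0
        else:
            raise CalibrationError("raw readings are not strictly monotone in concentration")
        order = np.argsort(self._sign * raw)
        self._raw = (self._sign * raw)[order]
        self._conc = conc[order]

    def __call__(self, raw) -> np.ndarray:
        x = self._sign * np.asarray(raw, dtype=float)
        y = np.interp(x, self._raw, self._conc)
        # linear extrapolation from the terminal segments, then clamp at 0 ppm
        lo_slope = (self._conc[1] - self._conc[0]) / (self._raw[1] - self._raw[0])
        hi_slope = (self._conc[-1] - self._conc[-2]) / (self._raw[-1] - self._raw[-2])
        y = np.where(x < self._raw[0], self._conc[0] + (x - self._raw[0]) * lo_slope, y)
        y = np.where(x > self._raw[-1], self._conc[-1] + (x - self._raw[-1]) * hi_slope, y)
        return np.maximum(y, 0.0)


@dataclass
class ConcentrationSeries:
    """NO2 per sample: ppm when calibrated, unitless in [0, 1] when relative."""

    no2: np.ndarray
    timestamps: np.ndarray | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.no2 = np.asarray(self.no2, dtype=float)
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)


def fit_calibration(
    points: list[CalibrationPoint], fitted_at: datetime | None = None
) -> CalibrationCurve:
    """Fit a monotone piecewise-linear curve through >= 2 calibration points."""
    if len(points) < 2:
        raise InsufficientDataError("need at least 2 calibration points")
    if fitted_at is None:
        return CalibrationCurve(list(points))
    return CalibrationCurve(list(points), fitted_at=fitted_at)


def apply_calibration(
    curve: CalibrationCurve, raw, timestamps=None
) -> ConcentrationSeries:
    """Map a raw series through the curve; negative extrapolations clamp to 0 ppm."""
    return ConcentrationSeries(curve(raw), timestamps=timestamps, is_relative=False)


def relative_concentration(raw, timestamps=None) -> ConcentrationSeries:
    """Min-max scale a journey's raw readings to [0, 1].

    A constant series has no relative variation and maps to all zeros
    (with a warning) rather than raising: a flat sensor trace is an
    observable outcome, not invalid input.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise EmptyInputError("cannot scale an empty series")
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi == lo:
        warnings.warn("constant raw series: no relative variation observed", stacklevel=2)
        rel = np.zeros(raw.size)
    else:
        rel = (raw - lo) / (hi - lo)
    return ConcentrationSeries(rel, timestamps=timestamps, is_relative=True)


def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read calibration points from a 2-column CSV ``concentration_ppm,raw_reading``."""
    df = pd.read_csv(path)
    for col in ("concentration_ppm", "raw_reading"):
        if col not in df.columns:
            raise CalibrationError(f"missing column {col!r} in {path}")
    return [
        CalibrationPoint(float(c), float(r))
        for c, r in zip(df["concentration_ppm"], df["raw_reading"])
    ]
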