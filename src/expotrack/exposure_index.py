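"""The indexed relative exposure: product of max-normalised NO2, depth and rate.

For each fused sample i of a journey,

    exposure_i = (NO2_i / max NO2) x (depth_i / max depth) x (rate_i / max rate)

with the maxima taken per journey over non-gap samples.  The index lives
on [0, 1]: 0 where any component is 0 (no pollutant, or no breathing) and
1 only at a sample where all three components are simultaneously at their
journey maxima.  Holding the maxima fixed, the index is linear in each
component separately — doubling one component of one sample doubles that
sample's exposure — while rescaling an entire component series changes
nothing (the normalisation absorbs it).

Maxima are deliberately per-journey: the index is a relative snapshot of
one person on one journey and must not be aggregated across journeys or
people to characterise places.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyInputError, ParameterError
from .track_fusion import FusedTrack

DEFAULT_N_BANDS = 5


@dataclass
class ExposureInputs:
    """Component series plus the per-journey maxima used for normalisation."""

    no2: np.ndarray
    depth: np.ndarray
    rate: np.ndarray
    max_no2: float
    max_depth: float
    max_rate: float

    @classmethod
    def from_series(cls, no2, depth, rate, mask=None) -> "ExposureInputs":
        """Build inputs with maxima computed over ``mask`` (non-gap) samples."""
        no2 = np.asarray(no2, dtype=float)
        depth = np.asarray(depth, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if mask is None:
            mask = np.ones(no2.size, dtype=bool)
        if not mask.any():
            raise EmptyInputError("no valid samples to take maxima over")
        return cls(
            no2=no2,
            depth=depth,
            rate=rate,
            max_no2=float(np.max(no2[mask])),
            max_depth=float(np.max(depth[mask])),
            max_rate=float(np.max(rate[mask])),
        )


def compute_exposure(inputs: ExposureInputs) -> np.ndarray:
    """Per-sample exposure index on [0, 1].

    A component whose journey maximum is 0 (e.g. no breaths detected at
    all) forces the whole index to 0, with a warning: such a journey is
    observable, not invalid.
    """
    no2 = np.asarray(inputs.no2, dtype=float)
    depth = np.asarray(inputs.depth, dtype=float)
    rate = np.asarray(inputs.rate, dtype=float)
    maxima = (inputs.max_no2, inputs.max_depth, inputs.max_rate)
    for name, s, m in zip(("no2", "depth", "rate"), (no2, depth, rate), maxima):
        finite = s[np.isfinite(s)]
        if np.any(finite < 0) or m < 0:
            raise DomainError(f"negative {name} values are outside the index domain")
        if m > 0 and finite.size and np.max(finite) > m * (1 + 1e-12):
            raise DomainError(f"{name} values exceed the stated journey maximum")
    if 0.0 in maxima:
        warnings.warn(
            "a component's journey maximum is 0; exposure is 0 everywhere", stacklevel=2
        )
        return np.zeros(no2.size)
    return (no2 / inputs.max_no2) * (depth / inputs.max_depth) * (rate / inputs.max_rate)


def band_labels(n_bands: int) -> list[str]:
    """Ordinal labels lowest ... highest for ``n_bands`` equal-width bins."""
    if n_bands < 2:
        raise ParameterError("n_bands must be >= 2")
    labels = [f"band {i}" for i in range(1, n_bands + 1)]
    labels[0] = "lowest"
    labels[-1] = "highest"
    return labels


def band_relative(exposure, n_bands: int = DEFAULT_N_BANDS) -> list[str]:
    """Equal-width ordinal bands on [0, 1], presented lowest -> highest.

    Boundary values fall in the upper bin (e.g. 0.5 with 4 bands is
    "band 3"), except 1.0 which stays in the top bin.
    """
    labels = band_labels(n_bands)
    x = np.asarray(exposure, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size and (np.any(finite < -1e-12) or np.any(finite > 1 + 1e-12)):
        raise DomainError("exposure values outside [0, 1] cannot be banded")
    safe = np.where(np.isfinite(x), np.clip(x, 0.0, 1.0), 0.0)
    idx = np.minimum(np.floor(safe * n_bands).astype(int), n_bands - 1)
    return [labels[i] if np.isfinite(v) else None for i, v in zip(idx, x)]


@dataclass
class ExposureTrack:
    """A fused track plus the per-sample index, banding and normalised components.

    Gap samples carry NaN exposure and ``None`` band; the ``maxima``
    mapping records the journey normalisation constants actually used.
    """

    timestamps: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    no2_rel: np.ndarray
    airflow_depth_rel: np.ndarray
    airflow_rate_rel: np.ndarray
    exposure: np.ndarray
    band: list
    gap_flags: np.ndarray
    maxima: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.timestamps.size


def attach_exposure(track: FusedTrack, n_bands: int = DEFAULT_N_BANDS) -> ExposureTrack:
    """Compute the index for every non-gap sample of a fused track.

    Maxima are recomputed over non-gap samples only; gap samples keep
    their position (when known) but carry no exposure value.
    """
    valid = ~track.gap_flags
    if not valid.any():
        raise EmptyInputError("all samples are gap-flagged; nothing to index")

    no2 = np.where(valid, track.no2, np.nan)
    depth = np.where(valid, track.airflow_depth, np.nan)
    rate = np.where(valid, track.airflow_rate, np.nan)
    inputs = ExposureInputs.from_series(no2, depth, rate, mask=valid)
    exposure = compute_exposure(inputs)
    exposure = np.where(valid, exposure, np.nan)
    band = band_relative(exposure, n_bands)

    def rel(series, maximum):
        if maximum <= 0:
            return np.zeros(series.size) + np.where(valid, 0.0, np.nan)
        return series / maximum

    return ExposureTrack(
        timestamps=track.timestamps,
        lat=track.lat,
        lon=track.lon,
        no2_rel=rel(no2, inputs.max_no2),
        airflow_depth_rel=rel(depth, inputs.max_depth),
        airflow_rate_rel=rel(rate, inputs.max_rate),
        exposure=exposure,
        band=band,
        gap_flags=track.gap_flags,
        maxima={
            "max_no2": inputs.max_no2,
            "max_depth": inputs.max_depth,
            "max_rate": inputs.max_rate,
        },
    )
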