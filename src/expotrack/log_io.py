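"""Reading/writing the sensor-logger CSV dialect and geospatial track exports.

The logger schema is one header row ``timestamp,lat,lon,<channel>[,...]``:
a timestamp (ISO 8601 or integer epoch-milliseconds), a WGS84 position in
decimal degrees, and one column per sensor channel (typically ``no2_raw``
and ``airflow_raw``).  Channel columns are discovered from the header so
the same reader serves any sensor combination.

Processed tracks can be exported as GeoJSON (RFC 7946) point collections
or GPX 1.1 tracks with exposure values carried in trackpoint extensions.
"""

from __future__ import annotations

import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, OrderingError

if TYPE_CHECKING:  # pragma: no cover
    from .exposure_index import ExposureTrack

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("timestamp", "lat", "lon")

_GPX_NS = "http://www.topografix.com/GPX/1/1"


def _iso_utc(epoch_s: float) -> str:
    """Millisecond-resolution ISO 8601 UTC string for an epoch-seconds value."""
    dt = datetime.fromtimestamp(round(epoch_s * 1000.0) / 1000.0, tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"


@dataclass
class RawSample:
    """One logger row: a timestamped, georeferenced set of raw channel readings."""

    timestamp: datetime
    lat: float
    lon: float
    channels: dict[str, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("sample has no channel readings")
        if not (-90.0 <= self.lat <= 90.0):
            raise FormatError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise FormatError(f"longitude {self.lon} outside [-180, 180]")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)

    @property
    def epoch_s(self) -> float:
        return self.timestamp.timestamp()


@dataclass
class SensorLog:
    """An ordered journey log; all samples share one channel set."""

    samples: list[RawSample] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples:
            chans = self.samples[0].channels.keys()
            for s in self.samples:
                if s.channels.keys() != chans:
                    raise FormatError("samples do not share a common channel set")
            t = self.times_s()
            if np.any(np.diff(t) <= 0):
                raise OrderingError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def channel_names(self) -> list[str]:
        return list(self.samples[0].channels) if self.samples else []

    def times_s(self) -> np.ndarray:
        """Epoch seconds (float64) for every sample."""
        return np.array([s.epoch_s for s in self.samples], dtype=float)

    def channel(self, name: str) -> np.ndarray:
        return np.array([s.channels[name] for s in self.samples], dtype=float)

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.array([s.lat for s in self.samples], dtype=float)
        lon = np.array([s.lon for s in self.samples], dtype=float)
        return lat, lon


def _numeric(col: pd.Series) -> np.ndarray:
    """Exact (round-trip) float parsing; NaN where unparseable."""

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return np.array([conv(x) for x in col], dtype=float)


def _parse_timestamps(col: pd.Series) -> np.ndarray:
    """Epoch seconds from ISO 8601 strings or integer epoch-milliseconds; NaN = unparseable."""
    numeric = _numeric(col)
    if np.isfinite(numeric).all():
        return numeric / 1000.0
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="mixed")
    sec = np.full(len(parsed), np.nan)
    mask = parsed.notna().to_numpy()
    if mask.any():
        sec[mask] = parsed[mask].astype("int64").to_numpy() / 1e9
    return sec


def read_log_csv(path, strict: bool = True) -> SensorLog:
    """Parse a logger CSV into a :class:`SensorLog`.

    In strict mode any malformed row or non-increasing timestamp raises; in
    lenient mode bad rows are skipped and counted in ``meta["skipped_rows"]``
    (field logs from low-cost hardware contain glitches).
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    for required in REQUIRED_COLUMNS:
        if required not in cols:
            raise FormatError(f"missing required column {required!r} in {path}")
    channel_cols = [c for c in cols if c not in REQUIRED_COLUMNS]
    if not channel_cols:
        raise FormatError(f"no channel columns found in {path}")

    if df.empty:
        return SensorLog([], {"skipped_rows": 0, "channels": channel_cols})

    t = _parse_timestamps(df["timestamp"])
    lat = _numeric(df["lat"])
    lon = _numeric(df["lon"])
    chan = {c: _numeric(df[c]) for c in channel_cols}

    bad = ~np.isfinite(t) | ~np.isfinite(lat) | ~np.isfinite(lon)
    bad |= (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)
    for v in chan.values():
        bad |= ~np.isfinite(v)
    if strict and bad.any():
        row = int(np.argmax(bad))
        raise FormatError(f"unparseable row {row} in {path}")

    keep = ~bad
    t_kept = t[keep]
    # enforce strictly increasing time: strict -> error, lenient -> drop offenders
    order_bad = np.zeros(t_kept.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t_kept):
        if ti <= last:
            order_bad[i] = True
        else:
            last = ti
    if order_bad.any():
        if strict:
            raise OrderingError(f"non-increasing timestamps in {path}")
        idx = np.flatnonzero(keep)[order_bad]
        keep[idx] = False
        bad[idx] = True

    samples = []
    for i in np.flatnonzero(keep):
        ts = datetime.fromtimestamp(t[i], tz=timezone.utc)
        samples.append(
            RawSample(ts, float(lat[i]), float(lon[i]), {c: float(chan[c][i]) for c in channel_cols})
        )
    skipped = int(bad.sum())
    if skipped:
        logger.warning("skipped %d malformed row(s) while reading %s", skipped, path)
    return SensorLog(samples, {"skipped_rows": skipped, "channels": channel_cols})


def write_log_csv(log: SensorLog, path) -> str:
    """Write a :class:`SensorLog` in the logger CSV dialect (ISO 8601 UTC timestamps).

    Floats are written with shortest round-trip precision, so
    ``read_log_csv(write_log_csv(log))`` reproduces values exactly.
    """
    channels = log.channel_names or list(log.meta.get("channels", []))
    header = list(REQUIRED_COLUMNS) + channels
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for s in log.samples:
            row = [_iso_utc(s.epoch_s), repr(s.lat), repr(s.lon)]
            row += [repr(s.channels[c]) for c in channels]
            fh.write(",".join(row) + "\n")
    return str(path)


def _track_properties(track: "ExposureTrack", i: int) -> dict:
    def val(x):
        f = float(x)
        return None if math.isnan(f) else f

    return {
        "timestamp": _iso_utc(float(track.timestamps[i])),
        "no2_rel": val(track.no2_rel[i]),
        "airflow_depth_rel": val(track.airflow_depth_rel[i]),
        "airflow_rate_rel": val(track.airflow_rate_rel[i]),
        "exposure": val(track.exposure[i]),
        "band": track.band[i],
    }


def export_geojson(track: "ExposureTrack", path) -> str:
    """Write an exposure track as a GeoJSON FeatureCollection of Points (lon, lat order)."""
    if len(track) == 0:
        raise EmptyInputError("cannot export an empty track")
    features = []
    for i in range(len(track)):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(track.lon[i]), float(track.lat[i])],
                },
                "properties": _track_properties(track, i),
            }
        )
    obj = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, allow_nan=False)
    return str(path)


def export_gpx(track: "ExposureTrack", path) -> str:
    """Write an exposure track as a single GPX 1.1 track; exposure values ride in extensions."""
    if len(track) == 0:
        raise EmptyInputError("cannot export an empty track")
    ET.register_namespace("", _GPX_NS)
    gpx = ET.Element(f"{{{_GPX_NS}}}gpx", {"version": "1.1", "creator": "expotrack"})
    trk = ET.SubElement(gpx, f"{{{_GPX_NS}}}trk")
    ET.SubElement(trk, f"{{{_GPX_NS}}}name").text = "expotrack journey"
    seg = ET.SubElement(trk, f"{{{_GPX_NS}}}trkseg")
    for i in range(len(track)):
        pt = ET.SubElement(
            seg,
            f"{{{_GPX_NS}}}trkpt",
            {"lat": repr(float(track.lat[i])), "lon": repr(float(track.lon[i]))},
        )
        ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = _iso_utc(float(track.timestamps[i]))
        ext = ET.SubElement(pt, f"{{{_GPX_NS}}}extensions")
        for key, value in _track_properties(track, i).items():
            if key == "timestamp":
                continue
            el = ET.SubElement(ext, key)
            el.text = "" if value is None else str(value)
    ET.indent(gpx)
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")
    return str(path)


def write_track_csv(track: "ExposureTrack", path) -> str:
    """Flat CSV of a processed track (one row per fused sample; empty cells at gaps)."""
    if len(track) == 0:
        raise EmptyInputError("cannot export an empty track")

    def cell(x):
        f = float(x)
        return "" if math.isnan(f) else repr(f)

    header = (
        "timestamp,lat,lon,no2_rel,airflow_depth_rel,airflow_rate_rel,exposure,band,gap"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        for i in range(len(track)):
            fh.write(
                ",".join(
                    [
                        _iso_utc(float(track.timestamps[i])),
                        repr(float(track.lat[i])),
                        repr(float(track.lon[i])),
                        cell(track.no2_rel[i]),
                        cell(track.airflow_depth_rel[i]),
                        cell(track.airflow_rate_rel[i]),
                        cell(track.exposure[i]),
                        track.band[i] or "",
                        "1" if track.gap_flags[i] else "0",
                    ]
                )
                + "\n"
            )
    return str(path)
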