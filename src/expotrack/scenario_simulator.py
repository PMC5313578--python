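"""Ground-truthed synthetic walking journeys in the logger CSV format.

A scenario is a contiguous chain of route segments (each a lat/lon
polyline with a zone label and gradient) plus a set of NO2 "hotspots".
The walker advances along the route at constant speed; per-second ground
truth is generated for

* **NO2** — a base level plus a sum of isotropic Gaussian kernels, one
  per hotspot (roadside concentrations fall off sharply within tens of
  metres, and a kernel is the simplest field with that property);
* **breathing** — a rest rate/depth that rises with first-order lag
  toward an exertion ceiling while on a steep climb; after the climb the
  rate keeps rising briefly (ventilation lags exertion) before decaying
  exponentially back to rest ("respiratory recovery"), while depth
  normalises faster with its own, shorter half-life.

From the truth the simulator synthesises a raw thermocouple-style airflow
waveform (quasi-sinusoid whose instantaneous period and peak amplitude
track the true rate and depth, plus slow baseline drift and Gaussian
noise) and emits a 1 Hz logger CSV whose NO2 channel is an affine sensor
response plus noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
from shapely.geometry import LineString

from .airflow_metrics import AirflowSeries
from .errors import EmptyInputError, ParameterError
from .log_io import RawSample, SensorLog, write_log_csv

EARTH_M_PER_DEG_LAT = 111_320.0

ZONES = ("traffic_control", "steep_climb", "residential", "park")


@dataclass(frozen=True)
class Hotspot:
    """An NO2 point source (e.g. a signalised junction): Gaussian kernel in space."""

    lat: float
    lon: float
    amplitude: float  # relative ppm added at the centre
    radius_m: float  # kernel sigma

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ParameterError("hotspot radius must be positive")


@dataclass(frozen=True)
class Segment:
    polyline: tuple  # ((lat, lon), ...) vertices
    zone: str
    gradient_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ParameterError(f"unknown zone {self.zone!r}; expected one of {ZONES}")
        if len(self.polyline) < 2:
            raise ParameterError("segment polyline needs at least 2 vertices")


@dataclass
class RouteScenario:
    segments: list[Segment]
    hotspots: list[Hotspot] = field(default_factory=list)
    walk_speed: float = 1.4  # m/s, comfortable walking pace

    def __post_init__(self) -> None:
        if not self.segments:
            raise EmptyInputError("scenario has no segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.polyline[-1] != b.polyline[0]:
                raise ParameterError("segments must be contiguous end-to-start")
        if self.walk_speed <= 0:
            raise ParameterError("walk_speed must be positive")


@dataclass
class SimParams:
    """Generative parameters for one simulated journey.

    NO2 quantities are in ppm (urban ambient NO2 is of order 0.01-0.05
    ppm); breathing rates in breaths/min span rest (~14) to brisk uphill
    effort (~28) for a fit adult walker.  Noise is expressed in each
    sensor's raw units and can be set to 0 for noise-free runs.
    """

    base_no2: float = 0.010  # ppm away from all sources
    breath_rest_rate: float = 14.0  # breaths/min at rest
    breath_climb_rate: float = 28.0  # breaths/min ceiling, reached in post-climb recovery
    climb_rate_fraction: float = 0.75  # fraction of the rest->ceiling rise reached while climbing
    breath_climb_depth_gain: float = 2.0  # depth multiplier at full exertion
    resp_response_tau_s: float = 20.0  # first-order lag of the breathing response
    post_exertion_rise_s: float = 15.0  # frequency keeps surging this long after the climb
    surge_tau_s: float = 5.0  # lag of the post-climb frequency surge
    recovery_halflife_s: float = 90.0  # rate decay back to rest (recovery takes minutes)
    depth_recovery_halflife_s: float = 15.0  # depth normalises much faster than rate
    rest_depth: float = 1.0  # raw units, relative tidal depth at rest
    airflow_fs_hz: float = 25.0  # waveform sampling rate
    airflow_noise_sd: float = 0.02  # raw units on the airflow waveform
    airflow_drift_amp: float = 0.3  # slow thermocouple baseline drift, raw units
    no2_raw_offset: float = 1000.0  # sensor raw units at 0 ppm
    no2_raw_slope: float = 20000.0  # raw units per ppm (affine sensor response)
    no2_noise_sd: float = 5.0  # raw units on the NO2 channel
    seed: int = 0
    start_time: datetime = field(
        default_factory=lambda: datetime(2016, 6, 1, 8, 0, tzinfo=timezone.utc)
    )

    def __post_init__(self) -> None:
        if self.breath_rest_rate <= 0 or self.breath_climb_rate <= 0:
            raise ParameterError("breathing rates must be positive")
        if self.recovery_halflife_s <= 0 or self.depth_recovery_halflife_s <= 0:
            raise ParameterError("recovery half-lives must be positive")
        if self.airflow_fs_hz <= 0:
            raise ParameterError("airflow_fs_hz must be positive")


@dataclass
class GroundTruth:
    """Per-second truth for one journey (times relative to journey start)."""

    t: np.ndarray  # seconds from start
    lat: np.ndarray
    lon: np.ndarray
    zone: np.ndarray  # zone label per sample
    no2: np.ndarray  # true concentration, ppm
    rate: np.ndarray  # true breaths/min
    depth: np.ndarray  # true relative depth, raw units
    start_time: datetime

    def __len__(self) -> int:
        return self.t.size


def _local_xy(lat, lon, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular metres relative to (lat0, lon0); fine at walking scale."""
    kx = EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0))
    return (np.asarray(lon, dtype=float) - lon0) * kx, (
        np.asarray(lat, dtype=float) - lat0
    ) * EARTH_M_PER_DEG_LAT


def no2_field(scenario: RouteScenario, params: SimParams, lat, lon) -> np.ndarray:
    """base + sum of hotspot Gaussian kernels, evaluated at (lat, lon)."""
    lat0 = scenario.segments[0].polyline[0][0]
    lon0 = scenario.segments[0].polyline[0][1]
    x, y = _local_xy(lat, lon, lat0, lon0)
    c = np.full(np.shape(x), params.base_no2, dtype=float)
    for h in scenario.hotspots:
        hx, hy = _local_xy(h.lat, h.lon, lat0, lon0)
        d2 = (x - hx) ** 2 + (y - hy) ** 2
        c += h.amplitude * np.exp(-d2 / (2.0 * h.radius_m**2))
    return c


def _breathing_truth(t: np.ndarray, zone: np.ndarray, params: SimParams):
    """Rate/depth response to climb exertion.

    While climbing, depth rises with first-order lag toward its full
    exertion gain, but frequency only rises toward a *fraction* of its
    ceiling (breath is managed during effort); when the climb ends,
    frequency surges quickly to the ceiling — the recovery hyperpnea that
    puts the frequency maximum *after* the climb — and both then decay
    exponentially back to rest, depth with the shorter half-life.
    """
    rest, ceil = params.breath_rest_rate, params.breath_climb_rate
    rate = np.full(t.size, rest)
    depth = np.full(t.size, params.rest_depth)
    climbing = zone == "steep_climb"
    if not climbing.any():
        return rate, depth
    edges = np.flatnonzero(np.diff(np.concatenate([[0], climbing.astype(int), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) is one climb interval
        t0, t1 = t[i0], t[i1 - 1]
        rise_end = t1 + params.post_exertion_rise_s

        def rise(tt, tau=params.resp_response_tau_s):
            return 1.0 - np.exp(-(tt - t0) / tau)

        climb_target = rest + params.climb_rate_fraction * (ceil - rest)
        mc = (t >= t0) & (t <= t1)
        rate[mc] = rest + (climb_target - rest) * rise(t[mc])
        r1 = rest + (climb_target - rest) * rise(t1)
        surge = (t > t1) & (t <= rise_end)
        rate[surge] = ceil + (r1 - ceil) * np.exp(-(t[surge] - t1) / params.surge_tau_s)
        peak = ceil + (r1 - ceil) * math.exp(-params.post_exertion_rise_s / params.surge_tau_s)
        after = t > rise_end
        rate[after] = rest + (peak - rest) * 2.0 ** (
            -(t[after] - rise_end) / params.recovery_halflife_s
        )
        gain = params.rest_depth * params.breath_climb_depth_gain
        depth[mc] = params.rest_depth + (gain - params.rest_depth) * rise(t[mc])
        d1 = params.rest_depth + (gain - params.rest_depth) * rise(t1)
        ad = t > t1
        depth[ad] = params.rest_depth + (d1 - params.rest_depth) * 2.0 ** (
            -(t[ad] - t1) / params.depth_recovery_halflife_s
        )
    return rate, depth


def simulate_route(
    scenario: RouteScenario, params: SimParams, interval_s: float = 1.0
) -> GroundTruth:
    """Walk the route at ``walk_speed`` and evaluate the ground truth per sample."""
    if interval_s <= 0:
        raise ParameterError("interval_s must be positive")
    lat0, lon0 = scenario.segments[0].polyline[0]
    lines = []
    cum = [0.0]
    for seg in scenario.segments:
        xs, ys = _local_xy(
            [p[0] for p in seg.polyline], [p[1] for p in seg.polyline], lat0, lon0
        )
        line = LineString(np.column_stack([xs, ys]))
        lines.append(line)
        cum.append(cum[-1] + line.length)
    total_len = cum[-1]
    duration = total_len / scenario.walk_speed
    n = int(math.floor(duration / interval_s)) + 1
    t = np.arange(n) * interval_s
    dist = t * scenario.walk_speed

    seg_idx = np.minimum(np.searchsorted(cum, dist, side="right") - 1, len(lines) - 1)
    x = np.empty(n)
    y = np.empty(n)
    for i, (si, d) in enumerate(zip(seg_idx, dist)):
        p = lines[si].interpolate(d - cum[si])
        x[i], y[i] = p.x, p.y
    lat = lat0 + y / EARTH_M_PER_DEG_LAT
    lon = lon0 + x / (EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0)))
    zone = np.array([scenario.segments[si].zone for si in seg_idx])

    no2 = no2_field(scenario, params, lat, lon)
    rate, depth = _breathing_truth(t, zone, params)
    return GroundTruth(
        t=t, lat=lat, lon=lon, zone=zone, no2=no2, rate=rate, depth=depth,
        start_time=params.start_time,
    )


def synthesize_airflow(truth: GroundTruth, params: SimParams) -> AirflowSeries:
    """Raw thermocouple-style waveform whose period and peak amplitude track the truth."""
    if len(truth) == 0:
        raise EmptyInputError("ground truth is empty")
    fs = params.airflow_fs_hz
    n = int(round(truth.t[-1] * fs)) + 1
    tt = np.arange(n) / fs
    rate = np.interp(tt, truth.t, truth.rate)
    depth = np.interp(tt, truth.t, truth.depth)
    phase = 2.0 * np.pi * np.cumsum(rate / 60.0) / fs
    drift = params.airflow_drift_amp * np.sin(2.0 * np.pi * tt / 300.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    noise = rng.normal(0.0, params.airflow_noise_sd, n) if params.airflow_noise_sd > 0 else 0.0
    return AirflowSeries(timestamps=tt, values=depth * np.sin(phase) + drift + noise,
                         sample_rate_hz=fs)


def no2_sensor_response(params: SimParams, concentration) -> np.ndarray:
    """The simulated sensor's noiseless affine response raw = offset + slope * ppm."""
    return params.no2_raw_offset + params.no2_raw_slope * np.asarray(concentration, float)


def _to_sensor_log(t_s, start_time, lat, lon, channels: dict) -> SensorLog:
    start = start_time.timestamp()
    samples = []
    for i, ti in enumerate(t_s):
        ts = datetime.fromtimestamp(start + float(ti), tz=timezone.utc)
        samples.append(
            RawSample(ts, float(lat[i]), float(lon[i]),
                      {k: float(v[i]) for k, v in channels.items()})
        )
    return SensorLog(samples, {"skipped_rows": 0})


def emit_log(
    truth: GroundTruth,
    airflow: AirflowSeries,
    params: SimParams,
    path,
    highrate_path=None,
) -> SensorLog:
    """Write the 1 Hz logger CSV (and optionally the high-rate airflow companion).

    The NO2 channel is the sensor's affine response to the true field plus
    Gaussian noise; the airflow channel carries the waveform sampled at
    the logging instants.  The high-rate companion file uses the same CSV
    dialect with positions interpolated along the walk, and is what the
    breath-metric stage should consume.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 2]))
    no2_raw = no2_sensor_response(params, truth.no2)
    if params.no2_noise_sd > 0:
        no2_raw = no2_raw + rng.normal(0.0, params.no2_noise_sd, len(truth))
    idx = np.minimum(
        np.round(truth.t * params.airflow_fs_hz).astype(int), len(airflow) - 1
    )
    log = _to_sensor_log(
        truth.t, truth.start_time, truth.lat, truth.lon,
        {"no2_raw": no2_raw, "airflow_raw": airflow.values[idx]},
    )
    write_log_csv(log, path)
    if highrate_path is not None:
        hf_lat = np.interp(airflow.timestamps, truth.t, truth.lat)
        hf_lon = np.interp(airflow.timestamps, truth.t, truth.lon)
        hf = _to_sensor_log(
            airflow.timestamps, truth.start_time, hf_lat, hf_lon,
            {"airflow_raw": airflow.values},
        )
        write_log_csv(hf, highrate_path)
    return log


def write_ground_truth_csv(truth: GroundTruth, path) -> str:
    """Truth table (for tests/validation): one row per second."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("t,lat,lon,zone,no2,rate,depth\n")
        for i in range(len(truth)):
            fh.write(
                f"{truth.t[i]!r},{truth.lat[i]!r},{truth.lon[i]!r},{truth.zone[i]},"
                f"{truth.no2[i]!r},{truth.rate[i]!r},{truth.depth[i]!r}\n"
            )
    return str(path)


def _offset(lat0: float, lon0: float, east_m: float, north_m: float) -> tuple[float, float]:
    return (
        lat0 + north_m / EARTH_M_PER_DEG_LAT,
        lon0 + east_m / (EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0))),
    )


def default_scenario(lat0: float = 54.047, lon0: float = -2.801) -> RouteScenario:
    """The packaged demonstration route: a ~1.2 km loop through four zones.

    Eastbound flat traffic-control street with two signalised-junction
    hotspots; a 200 m climb at 10% grade; a westbound residential street
    (a broad, low-amplitude kernel models its distributed light traffic);
    and a park descent back to the start.
    """
    p = lambda e, n: _offset(lat0, lon0, e, n)
    segments = [
        Segment((p(0, 0), p(400, 0)), "traffic_control", 0.0),
        Segment((p(400, 0), p(400, 200)), "steep_climb", 10.0),
        Segment((p(400, 200), p(0, 200)), "residential", 0.0),
        Segment((p(0, 200), p(0, 0)), "park", -10.0),
    ]
    hotspots = [
        Hotspot(*p(120, 0), amplitude=0.040, radius_m=30.0),
        Hotspot(*p(300, 0), amplitude=0.045, radius_m=30.0),
        Hotspot(*p(200, 200), amplitude=0.028, radius_m=140.0),  # residential background
    ]
    return RouteScenario(segments=segments, hotspots=hotspots, walk_speed=1.4)


def simulate_journey(
    scenario: RouteScenario | None = None,
    params: SimParams | None = None,
    seed: int | None = None,
) -> tuple[GroundTruth, AirflowSeries]:
    """One-call simulation with defaults; ``seed`` overrides ``params.seed``."""
    scenario = scenario or default_scenario()
    params = params or SimParams()
    if seed is not None:
        params = replace(params, seed=int(seed))
    truth = simulate_route(scenario, params)
    return truth, synthesize_airflow(truth, params)
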