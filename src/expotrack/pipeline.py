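"""End-to-end orchestration: read -> calibrate/normalise -> breathe -> fuse -> index -> export.

The pipeline is a plain library function (:func:`run_process`) driven by a
:class:`PipelineConfig`; the CLI is a thin shell over it.  Every run is
reproducible from its config and inputs alone, and the run report records
the parameter values, skipped-row and gap counts, and the journey maxima
used as the index normalisation constants.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import airflow_metrics, log_io, no2_calibration, scenario_simulator, track_fusion
from .errors import ConfigError
from .exposure_index import ExposureTrack, attach_exposure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for one processing run; see module docs for units."""

    input_log: str | None = None
    highrate_airflow: str | None = None  # optional high-rate airflow CSV companion
    calibration_csv: str | None = None
    mode: str = "relative"  # "relative" (index only) or "calibrated" (ppm)
    window_s: float = airflow_metrics.DEFAULT_WINDOW_S
    min_prominence: float | None = None
    min_period_s: float = airflow_metrics.DEFAULT_MIN_PERIOD_S
    interval_s: float = 1.0
    max_gap_s: float = track_fusion.DEFAULT_MAX_GAP_S
    n_bands: int = 5
    strict: bool = False
    seed: int = 0
    geojson_out: str | None = None
    gpx_out: str | None = None
    csv_out: str | None = None
    report_out: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "calibrated"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "calibrated" and not self.calibration_csv:
            raise ConfigError("calibrated mode requires calibration_csv")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_process(config: PipelineConfig) -> tuple[ExposureTrack, dict]:
    """Execute the full processing chain and write any configured exports.

    Returns the exposure track and a run report sufficient to restate
    every normalisation constant used.
    """
    if not config.input_log:
        raise ConfigError("input_log is required")
    if not Path(config.input_log).exists():
        raise ConfigError(f"input log not found: {config.input_log}")
    if config.calibration_csv and not Path(config.calibration_csv).exists():
        raise ConfigError(f"calibration file not found: {config.calibration_csv}")

    log = log_io.read_log_csv(config.input_log, strict=config.strict)
    if "no2_raw" not in log.channel_names or "airflow_raw" not in log.channel_names:
        raise ConfigError("input log must carry no2_raw and airflow_raw channels")

    # airflow source: high-rate companion if provided, else the logged channel
    if config.highrate_airflow:
        if not Path(config.highrate_airflow).exists():
            raise ConfigError(f"high-rate airflow file not found: {config.highrate_airflow}")
        hf = log_io.read_log_csv(config.highrate_airflow, strict=config.strict)
        hf_t = hf.times_s()
        fs = 1.0 / float(np.median(np.diff(hf_t)))
        series = airflow_metrics.AirflowSeries(hf_t, hf.channel("airflow_raw"), fs)
        hf_skipped = hf.meta["skipped_rows"]
    else:
        t = log.times_s()
        fs = 1.0 / float(np.median(np.diff(t))) if len(log) > 1 else 1.0
        series = airflow_metrics.AirflowSeries(t, log.channel("airflow_raw"), fs)
        hf_skipped = None

    grid = track_fusion.build_grid(log, config.interval_s)
    metrics = airflow_metrics.breath_metrics(
        series, grid,
        window_s=config.window_s,
        min_prominence=config.min_prominence,
        min_period_s=config.min_period_s,
    )

    raw_no2 = log.channel("no2_raw")
    log_t = log.times_s()
    if config.mode == "calibrated":
        points = no2_calibration.read_calibration_csv(config.calibration_csv)
        curve = no2_calibration.fit_calibration(points)
        conc = no2_calibration.apply_calibration(curve, raw_no2, timestamps=log_t)
    else:
        conc = no2_calibration.relative_concentration(raw_no2, timestamps=log_t)

    lat, lon = log.positions()
    fused = track_fusion.align(
        grid, (log_t, lat, lon), conc, metrics, max_gap_s=config.max_gap_s
    )
    track = attach_exposure(fused, n_bands=config.n_bands)

    outputs = {}
    if config.geojson_out:
        outputs["geojson"] = log_io.export_geojson(track, config.geojson_out)
    if config.gpx_out:
        outputs["gpx"] = log_io.export_gpx(track, config.gpx_out)
    if config.csv_out:
        outputs["csv"] = log_io.write_track_csv(track, config.csv_out)

    report = {
        "config": config.to_dict(),
        "n_samples": len(track),
        "skipped_rows": log.meta["skipped_rows"],
        "highrate_skipped_rows": hf_skipped,
        "gap_count": int(track.gap_flags.sum()),
        "maxima": track.maxima,
        "airflow_sample_rate_hz": fs,
        "outputs": outputs,
        "errors": [],
    }
    if config.report_out:
        with open(config.report_out, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return track, report


@dataclass
class SimulateConfig:
    """Configuration for a simulation run; scenario defaults to the packaged loop."""

    out_dir: str = "."
    seed: int = 0
    duration_s: float | None = None  # truncate the journey after this many seconds
    params: dict = field(default_factory=dict)  # SimParams overrides
    scenario: dict | None = None  # optional explicit scenario description

    @classmethod
    def from_yaml(cls, path) -> "SimulateConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _scenario_from_dict(data: dict) -> scenario_simulator.RouteScenario:
    try:
        segments = [
            scenario_simulator.Segment(
                tuple(tuple(p) for p in seg["polyline"]),
                seg["zone"],
                float(seg.get("gradient_pct", 0.0)),
            )
            for seg in data["segments"]
        ]
        hotspots = [
            scenario_simulator.Hotspot(
                float(h["lat"]), float(h["lon"]),
                float(h["amplitude"]), float(h["radius_m"]),
            )
            for h in data.get("hotspots", [])
        ]
        return scenario_simulator.RouteScenario(
            segments=segments,
            hotspots=hotspots,
            walk_speed=float(data.get("walk_speed", 1.4)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid scenario description: {exc}") from exc


def run_simulate(config: SimulateConfig) -> dict:
    """Generate a synthetic journey; write logger CSV, high-rate airflow and truth CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = (
        _scenario_from_dict(config.scenario)
        if config.scenario
        else scenario_simulator.default_scenario()
    )
    try:
        params = scenario_simulator.SimParams(seed=config.seed, **config.params)
    except TypeError as exc:
        raise ConfigError(f"invalid simulation params: {exc}") from exc

    truth = scenario_simulator.simulate_route(scenario, params)
    if config.duration_s is not None:
        n = int(config.duration_s) + 1
        truth = scenario_simulator.GroundTruth(
            t=truth.t[:n], lat=truth.lat[:n], lon=truth.lon[:n], zone=truth.zone[:n],
            no2=truth.no2[:n], rate=truth.rate[:n], depth=truth.depth[:n],
            start_time=truth.start_time,
        )
    airflow = scenario_simulator.synthesize_airflow(truth, params)
    log_path = out / "log.csv"
    hf_path = out / "airflow_highrate.csv"
    truth_path = out / "ground_truth.csv"
    scenario_simulator.emit_log(truth, airflow, params, log_path, highrate_path=hf_path)
    scenario_simulator.write_ground_truth_csv(truth, truth_path)
    return {
        "log": str(log_path),
        "highrate_airflow": str(hf_path),
        "ground_truth": str(truth_path),
        "n_samples": len(truth),
        "seed": config.seed,
    }
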