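import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import expotrack as ex

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

SIM_SEED = 1


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """One default simulated journey (seed fixed), emitted to disk once per session."""
    out = tmp_path_factory.mktemp("sim")
    params = ex.SimParams(seed=SIM_SEED)
    truth = ex.simulate_route(ex.default_scenario(), params)
    airflow = ex.synthesize_airflow(truth, params)
    ex.emit_log(truth, airflow, params, out / "log.csv", highrate_path=out / "hf.csv")
    return {"dir": out, "truth": truth, "airflow": airflow, "params": params,
            "log": out / "log.csv", "hf": out / "hf.csv"}


@pytest.fixture(scope="session")
def processed(sim_dir):
    """The default journey run through the full pipeline."""
    track, report = ex.run_process(
        ex.PipelineConfig(
            input_log=str(sim_dir["log"]), highrate_airflow=str(sim_dir["hf"])
        )
    )
    return {"track": track, "report": report, "truth": sim_dir["truth"]}


def make_track(n=4, exposure=None, gap=None):
    """A small synthetic ExposureTrack for export tests."""
    from expotrack.exposure_index import ExposureTrack, band_relative

    t = 1.7e9 + np.arange(n, dtype=float)
    exposure = np.linspace(0, 1, n) if exposure is None else np.asarray(exposure, float)
    gap = np.zeros(n, dtype=bool) if gap is None else np.asarray(gap, bool)
    return ExposureTrack(
        timestamps=t,
        lat=54.0 + 0.0001 * np.arange(n),
        lon=-2.8 + 0.0001 * np.arange(n),
        no2_rel=np.where(gap, np.nan, np.linspace(0.2, 1, n)),
        airflow_depth_rel=np.where(gap, np.nan, np.full(n, 0.5)),
        airflow_rate_rel=np.where(gap, np.nan, np.full(n, 0.8)),
        exposure=np.where(gap, np.nan, exposure),
        band=band_relative(np.where(gap, np.nan, exposure)),
        gap_flags=gap,
        maxima={"max_no2": 1.0, "max_depth": 2.0, "max_rate": 28.0},
    )
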