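"""Logger CSV dialect round-trips and geospatial exports."""

import json
import xml.etree.ElementTree as ET
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from expotrack import (
    RawSample,
    SensorLog,
    export_geojson,
    export_gpx,
    read_log_csv,
    write_log_csv,
)
from expotrack.errors import EmptyInputError, FormatError, OrderingError

from conftest import make_track


def sample(i, **chan):
    ts = datetime(2016, 6, 1, 8, 0, i, tzinfo=timezone.utc)
    chan = chan or {"no2_raw": 1000.0 + i, "airflow_raw": 0.1 * i}
    return RawSample(ts, 54.0 + 1e-4 * i, -2.8 + 1e-4 * i, chan)


def test_roundtrip_preserves_values_and_order(tmp_path):
    log = SensorLog([sample(i) for i in range(3)])
    path = tmp_path / "log.csv"
    write_log_csv(log, path)
    back = read_log_csv(path, strict=True)
    assert len(back) == 3
    assert back.channel_names == ["no2_raw", "airflow_raw"]
    for a, b in zip(log.samples, back.samples):
        assert a.timestamp == b.timestamp
        assert a.lat == b.lat and a.lon == b.lon
        assert a.channels == b.channels


@given(
    st.lists(
        st.tuples(
            st.floats(-90, 90, allow_nan=False),
            st.floats(-180, 180, allow_nan=False),
            st.floats(-1e12, 1e12, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_roundtrip_lossless_for_finite_values(tmp_path_factory, rows):
    log = SensorLog(
        [
            RawSample(
                datetime.fromtimestamp(1.7e9 + i, tz=timezone.utc),
                lat, lon, {"no2_raw": v},
            )
            for i, (lat, lon, v) in enumerate(rows)
        ]
    )
    path = tmp_path_factory.mktemp("rt") / "log.csv"
    write_log_csv(log, path)
    back = read_log_csv(path)
    assert [s.channels["no2_raw"] for s in back.samples] == [r[2] for r in rows]
    assert [s.lat for s in back.samples] == [r[0] for r in rows]


def test_header_only_file_gives_empty_log(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("timestamp,lat,lon,no2_raw,airflow_raw\n")
    log = read_log_csv(path)
    assert len(log) == 0
    assert log.meta["skipped_rows"] == 0


def test_lenient_mode_skips_bad_rows_and_counts(tmp_path):
    rows = [
        "2016-06-01T08:00:00.000Z,54.0,-2.8,1000,0.1",
        "2016-06-01T08:00:01.000Z,54.0,-2.8,1001,0.2",
        "2016-06-01T08:00:02.000Z,notanumber,-2.8,1002,0.3",
        "2016-06-01T08:00:03.000Z,54.0,-2.8,1003,0.4",
        "2016-06-01T08:00:04.000Z,54.0,-2.8,1004,0.5",
    ]
    path = tmp_path / "bad.csv"
    path.write_text("timestamp,lat,lon,no2_raw,airflow_raw\n" + "\n".join(rows) + "\n")
    log = read_log_csv(path, strict=False)
    assert len(log) == 4
    assert log.meta["skipped_rows"] == 1
    with pytest.raises(FormatError):
        read_log_csv(path, strict=True)


def test_missing_required_column_is_a_format_error(tmp_path):
    path = tmp_path / "noheader.csv"
    path.write_text("timestamp,lat,no2_raw\n")
    with pytest.raises(FormatError):
        read_log_csv(path)


def test_non_increasing_timestamps(tmp_path):
    path = tmp_path / "order.csv"
    path.write_text(
        "timestamp,lat,lon,no2_raw\n"
        "2016-06-01T08:00:01.000Z,54.0,-2.8,1\n"
        "2016-06-01T08:00:00.000Z,54.0,-2.8,2\n"
        "2016-06-01T08:00:02.000Z,54.0,-2.8,3\n"
    )
    with pytest.raises(OrderingError):
        read_log_csv(path, strict=True)
    log = read_log_csv(path, strict=False)
    assert len(log) == 2
    assert log.meta["skipped_rows"] == 1


def test_epoch_millisecond_timestamps_accepted(tmp_path):
    path = tmp_path / "epoch.csv"
    path.write_text("timestamp,lat,lon,no2_raw\n1700000000500,54.0,-2.8,7\n")
    log = read_log_csv(path)
    assert log.samples[0].epoch_s == pytest.approx(1.7000000005e9)


def test_geojson_export_structure(tmp_path):
    track = make_track(n=2, exposure=[0.0, 1.0])
    path = tmp_path / "t.geojson"
    export_geojson(track, path)
    obj = json.loads(path.read_text())
    assert obj["type"] == "FeatureCollection"
    assert len(obj["features"]) == 2
    f0 = obj["features"][0]
    # coordinates are lon, lat and exposure 0 is serialized, not omitted
    assert f0["geometry"]["coordinates"] == [track.lon[0], track.lat[0]]
    assert f0["properties"]["exposure"] == 0.0
    lats = [f["geometry"]["coordinates"][1] for f in obj["features"]]
    assert min(lats) >= track.lat.min() and max(lats) <= track.lat.max()


def test_gpx_export_roundtrip(tmp_path):
    track = make_track(n=10)
    path = tmp_path / "t.gpx"
    export_gpx(track, path)
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    pts = root.findall(".//g:trkpt", ns)
    assert len(pts) == 10
    for i, pt in enumerate(pts):
        assert float(pt.get("lat")) == pytest.approx(track.lat[i], abs=1e-6)
        assert float(pt.get("lon")) == pytest.approx(track.lon[i], abs=1e-6)
        time = pt.find("g:time", ns).text
        assert time.endswith("Z")


def test_empty_track_export_raises(tmp_path):
    track = make_track(n=1)
    track.timestamps = np.array([])
    with pytest.raises(EmptyInputError):
        export_geojson(track, tmp_path / "x.geojson")
    with pytest.raises(EmptyInputError):
        export_gpx(track, tmp_path / "x.gpx")
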