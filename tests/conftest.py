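import io

import pytest

from hareport import trajectory_io as tio
from hareport.pipeline import RunConfig, run_pipeline
from hareport.synthetic import make_airfield, scenario_study_like, write_scenario


@pytest.fixture(scope="session")
def airfield():
    return make_airfield()


@pytest.fixture(scope="session")
def scenario():
    """The desk-scale study analogue: 5 animals, 30 days, seed 42."""
    return scenario_study_like(seed=42, n_days=30)


@pytest.fixture(scope="session")
def scenario_trajectories(scenario):
    buf = io.StringIO()
    scenario.fixes.to_csv(buf, index=False)
    buf.seek(0)
    return tio.read_gps_table(buf, projection=scenario.projection)


@pytest.fixture(scope="session")
def pipeline_result(scenario, tmp_path_factory):
    base = tmp_path_factory.mktemp("pipeline")
    paths = write_scenario(scenario, base / "sim")
    cfg = RunConfig(
        gps_csv=paths["fixes"],
        map_geojson=paths["airfield"],
        out_dir=str(base / "out"),
        site_lat=scenario.config.site_lat,
        site_lon=scenario.config.site_lon,
    )
    return run_pipeline(cfg)


def make_fix_csv(rows) -> io.StringIO:
    """Small GPS CSV from (animal_id, timestamp, lon, lat, accuracy) tuples."""
    buf = io.StringIO()
    buf.write("animal_id,timestamp,lon,lat,h_accuracy\n")
    for r in rows:
        buf.write(",".join("" if v is None else str(v) for v in r) + "\n")
    buf.seek(0)
    return buf
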