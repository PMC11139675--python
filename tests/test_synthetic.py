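import io
from datetime import date

import numpy as np
import pandas as pd
import pytest

from hareport import trajectory_io as tio
from hareport.airfield_geometry import dump_surface_map, tarmacked_subset
from hareport.interactions import detect_interactions
from hareport.movement import daily_distance
from hareport.solar import SunTimeSource
from hareport.synthetic import (
    AirfieldLayout,
    SimConfig,
    make_airfield,
    simulate_hares,
)


class TestMakeAirfield:
    def test_every_habitat_class_present(self, airfield):
        classes = {p.habitat_class for p in airfield.polygons}
        assert classes == {
            "tarmac_runway", "tarmac_taxiway", "tarmac_connecting",
            "apron", "built_land", "grassland", "service_road", "unknown",
        }

    def test_runway_width_is_60m(self, airfield):
        runway = next(p for p in airfield.polygons if p.surface_id == "RWY-N")
        minx, miny, maxx, maxy = runway.geometry.bounds
        assert maxy - miny == pytest.approx(60.0)
        taxiway = next(p for p in airfield.polygons if p.surface_id == "TWY-N")
        minx, miny, maxx, maxy = taxiway.geometry.bounds
        assert maxy - miny == pytest.approx(35.0)

    def test_deterministic_geojson(self, tmp_path, airfield):
        p1, p2 = tmp_path / "a.geojson", tmp_path / "b.geojson"
        dump_surface_map(make_airfield(), p1)
        dump_surface_map(make_airfield(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_overlapping_layout_rejected(self):
        # taxiway widened until it overlaps the runway band
        with pytest.raises(ValueError, match="overlap"):
            make_airfield(AirfieldLayout(taxiway_width_m=200.0))


class TestSimulateHares:
    def test_reproducible_from_seed(self, airfield):
        cfg = SimConfig(seed=9, n_animals=2, n_days=4)
        f1, _ = simulate_hares(airfield, cfg)
        f2, _ = simulate_hares(airfield, cfg)
        pd.testing.assert_frame_equal(f1, f2)

    def test_different_seed_differs(self, airfield):
        f1, _ = simulate_hares(airfield, SimConfig(seed=1, n_animals=1, n_days=2))
        f2, _ = simulate_hares(airfield, SimConfig(seed=2, n_animals=1, n_days=2))
        assert not f1.equals(f2)

    def test_active_fix_interval_is_10min(self, scenario):
        fixes = scenario.fixes
        one = fixes[fixes["animal_id"] == "H01"]
        ts = pd.to_datetime(one["timestamp"])
        gaps = ts.diff().dt.total_seconds().dropna() / 60.0
        # most gaps are exactly the active schedule; resting gaps are ~6 h
        assert (gaps == 10.0).mean() > 0.5
        assert gaps.min() >= 10.0
        assert gaps.max() <= 361.0

    def test_fraction_of_poor_accuracy_fixes(self, scenario):
        acc = scenario.fixes["h_accuracy"]
        frac = (acc > 30.0).mean()
        assert frac == pytest.approx(0.02, abs=0.01)

    def test_crepuscular_fix_pattern(self, scenario):
        # active fixes cluster within ~2 h of sunrise and sunset
        cfg = scenario.config
        sun = SunTimeSource(cfg.site_lat, cfg.site_lon, cfg.tz)
        ts = pd.to_datetime(scenario.fixes["timestamp"], utc=True)
        local = ts.dt.tz_convert("Europe/Dublin")
        near = 0
        for t in local:
            sd = sun(t.date())
            dr = abs((t - sd.sunrise_local).total_seconds()) / 3600.0
            ds = abs((t - sd.sunset_local).total_seconds()) / 3600.0
            if min(dr, ds) <= 2.0:
                near += 1
        share = near / len(local)
        # twilight windows cover 8/24 h of the day but hold most fixes
        assert share > 0.5

    def test_truth_crossings_lie_on_tarmac(self, scenario):
        tarmac_ids = {p.surface_id for p in tarmacked_subset(scenario.surface_map)}
        assert set(scenario.truth.crossings["surface_id"]) <= tarmac_ids

    def test_truth_daily_length_bounds_fix_based_distance(self, scenario):
        # straight-line steps under-measure the dense true path
        buf = io.StringIO()
        scenario.fixes.to_csv(buf, index=False)
        buf.seek(0)
        trajs = tio.read_gps_table(buf, projection=scenario.projection)
        truth = scenario.truth.daily_path_km
        for traj in trajs:
            steps = tio.build_steps(traj)
            dd = daily_distance(steps)
            merged = dd.merge(
                truth[truth["animal_id"] == traj.animal_id], on=["animal_id", "date"]
            )
            # allow GPS-noise slack of a few metres per fix
            assert (merged["distance_km"] <= merged["true_km"] + 0.5).all()

    def test_zero_noise_recall_of_straddled_crossings(self, airfield):
        # with no GPS noise, every true crossing containing a fix instant
        # must be recovered by segment-polygon detection
        cfg = SimConfig(
            seed=3, n_animals=2, n_days=10,
            noise_per_accuracy=0.0, frac_accuracy_over_30=0.0,
        )
        fixes, truth = simulate_hares(airfield, cfg)
        buf = io.StringIO()
        fixes.to_csv(buf, index=False)
        buf.seek(0)
        from hareport.projection import TransverseMercator

        trajs = tio.read_gps_table(
            buf, projection=TransverseMercator(cfg.site_lon, cfg.site_lat)
        )
        detected = set()
        fix_times = {}
        for traj in trajs:
            fix_times[traj.animal_id] = [f.t_utc for f in traj.fixes]
            for e in detect_interactions(tio.build_steps(traj), airfield):
                detected.add(
                    (e.animal_id, e.surface_id, e.step.fix_a.t_utc, e.step.fix_b.t_utc)
                )
        missed = 0
        covered = 0
        for _, row in truth.crossings.iterrows():
            times = fix_times.get(row["animal_id"], [])
            inside = [t for t in times if row["t_entry"] <= t <= row["t_exit"]]
            if not inside:
                continue  # crossing fell entirely between fixes
            covered += 1
            hit = any(
                a == row["animal_id"] and s == row["surface_id"]
                and ta <= inside[-1] and inside[0] <= tb
                for (a, s, ta, tb) in detected
            )
            if not hit:
                missed += 1
        assert covered > 0
        assert missed == 0

    def test_scripted_single_crossing(self, airfield):
        # a ballistic animal started south of runway N and headed nowhere
        # particular still gives consistent truth/detection bookkeeping;
        # here we force a crossing with a two-fix hand-made trajectory
        rows = [
            ("X", "2022-01-10T06:00:00Z"),
            ("X", "2022-01-10T06:10:00Z"),
        ]
        from hareport.projection import TransverseMercator

        proj = TransverseMercator(-6.2499, 53.4264)
        # x=500 avoids the connecting strips at x in {-1000, 0, 1000}
        lon0, lat0 = proj.inverse(500.0, 200.0)  # south of runway N (y 270..330)
        lon1, lat1 = proj.inverse(500.0, 400.0)  # north of it
        buf = io.StringIO()
        buf.write("animal_id,timestamp,lon,lat,h_accuracy\n")
        buf.write(f"X,{rows[0][1]},{lon0},{lat0},5\nX,{rows[1][1]},{lon1},{lat1},5\n")
        buf.seek(0)
        (traj,) = tio.read_gps_table(buf, projection=proj)
        events = detect_interactions(tio.build_steps(traj), airfield)
        assert [e.surface_id for e in events] == ["RWY-N"]

    def test_period_shorter_than_burn_in_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_days=0)


class TestScenario:
    def test_five_animals_30_days(self, scenario):
        assert scenario.fixes["animal_id"].nunique() == 5
        dates = pd.to_datetime(scenario.fixes["timestamp"]).dt.date
        assert (max(dates) - min(dates)).days == pytest.approx(30, abs=1)
        assert min(dates) == date(2021, 12, 5)

    def test_near_tarmac_animals_dominate_interactions(
        self, scenario, scenario_trajectories
    ):
        rates = {}
        for traj in scenario_trajectories:
            ft = tio.filter_fixes(traj).trajectory
            events = detect_interactions(tio.build_steps(ft), scenario.surface_map)
            days = max(
                (ft.fixes[-1].t_local.date() - ft.fixes[0].t_local.date()).days, 1
            )
            rates[traj.animal_id] = len(events) / days
        near = np.mean([rates["H01"], rates["H02"]])
        far = np.mean([rates["H03"], rates["H04"], rates["H05"]])
        assert near >= 10.0 * far

    def test_every_animal_interacts_but_sparsely(self, scenario, scenario_trajectories):
        for traj in scenario_trajectories:
            ft = tio.filter_fixes(traj).trajectory
            steps = tio.build_steps(ft)
            events = detect_interactions(steps, scenario.surface_map)
            share = len({id(e.step) for e in events}) / len(steps) * 100.0
            assert 0.0 < share < 20.0, traj.animal_id
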