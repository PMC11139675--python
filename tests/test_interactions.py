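from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest
import shapely
from shapely.geometry import box
from shapely.affinity import translate

from hareport.airfield_geometry import SurfaceMap, SurfacePolygon
from hareport.interactions import (
    breakdown_from_counts,
    category_breakdown,
    daily_counts,
    detect_interactions,
    mean_daily_rate,
    monthly_summary,
    population_extrapolation,
    trimmed_mean_excluding,
)
from hareport.trajectory_io import Fix, Step, to_local_time

UTC = timezone.utc


def _step(x0, y0, x1, y1, t=datetime(2022, 1, 10, 6, tzinfo=UTC), animal="a"):
    def fx(x, y, tt):
        return Fix(animal, tt, to_local_time(tt, "Europe/Dublin"), x, y, 0.0, 0.0, 5.0)

    length = float(np.hypot(x1 - x0, y1 - y0))
    return Step(
        animal_id=animal,
        fix_a=fx(x0, y0, t),
        fix_b=fx(x1, y1, t + timedelta(minutes=10)),
        length_m=length,
        duration_s=600.0,
        degenerate=(length == 0.0),
    )


def _map(*polys):
    return SurfaceMap(list(polys))


RUNWAY = SurfacePolygon("R1", box(0, 100, 3000, 160), "tarmac_runway", "active", "R1")
TAXIWAY = SurfacePolygon("T1", box(0, 0, 3000, 35), "tarmac_taxiway", "active", "T1")
GRASS = SurfacePolygon("G1", box(0, 300, 3000, 800), "grassland")


class TestDetectInteractions:
    def test_full_runway_crossing_is_one_event(self):
        events = detect_interactions([_step(100, 50, 100, 200)], _map(RUNWAY, GRASS))
        assert len(events) == 1
        assert events[0].surface_id == "R1"
        assert events[0].category == "runway"

    def test_crossing_runway_and_taxiway_gives_two_events(self):
        events = detect_interactions([_step(100, -10, 100, 200)], _map(RUNWAY, TAXIWAY))
        assert [e.surface_id for e in events] == ["R1", "T1"]

    def test_segment_in_grassland_gives_nothing(self):
        events = detect_interactions([_step(100, 400, 200, 500)], _map(RUNWAY, GRASS))
        assert events == []

    def test_boundary_touch_counts(self):
        # segment ends exactly on the runway's lower edge
        events = detect_interactions([_step(100, 50, 100, 100)], _map(RUNWAY))
        assert len(events) == 1

    def test_reentry_same_polygon_counts_once(self):
        # long shallow segment crossing the same runway twice still yields
        # one (step, polygon) event
        notch = SurfacePolygon(
            "N", box(0, 100, 3000, 160).difference(box(140, 90, 160, 170)),
            "tarmac_runway", "active", "N",
        )
        events = detect_interactions([_step(100, 130, 200, 130)], _map(notch))
        assert len(events) == 1

    def test_degenerate_steps_skipped(self):
        inside = _step(100, 130, 100, 130)
        assert inside.degenerate
        assert detect_interactions([inside], _map(RUNWAY)) == []

    def test_empty_tarmac_map_is_config_error(self):
        with pytest.raises(ValueError, match="tarmac"):
            detect_interactions([_step(0, 0, 1, 1)], _map(GRASS))

    def test_translation_invariance(self):
        steps = [_step(100, 50, 100, 200), _step(500, -10, 600, 300)]
        events = detect_interactions(steps, _map(RUNWAY, TAXIWAY))
        dx, dy = 12345.0, -678.0
        moved_steps = [
            _step(s.fix_a.x + dx, s.fix_a.y + dy, s.fix_b.x + dx, s.fix_b.y + dy)
            for s in steps
        ]
        moved_map = _map(
            *[
                SurfacePolygon(p.surface_id, translate(p.geometry, dx, dy),
                               p.habitat_class, p.activity_status, p.label)
                for p in (RUNWAY, TAXIWAY)
            ]
        )
        moved = detect_interactions(moved_steps, moved_map)
        assert [(e.surface_id,) for e in moved] == [(e.surface_id,) for e in events]

    def test_adding_polygon_never_decreases_events(self):
        steps = [_step(100, 50, 100, 200), _step(100, -10, 100, 20)]
        base = detect_interactions(steps, _map(RUNWAY))
        more = detect_interactions(steps, _map(RUNWAY, TAXIWAY))
        assert len(more) >= len(base)

    def test_matches_dense_sampling_oracle(self):
        # 300 random segments vs 5 random rectangles, versus a 1 cm
        # point-in-polygon sampling oracle
        rng = np.random.default_rng(77)
        rects = []
        for i in range(5):
            x, y = rng.uniform(0, 400, 2)
            w, h = rng.uniform(20, 120, 2)
            rects.append(
                SurfacePolygon(f"S{i}", box(x, y, x + w, y + h),
                               "tarmac_runway", "active", f"S{i}")
            )
        smap = _map(*rects)
        steps = [
            _step(*rng.uniform(-50, 500, 4), t=datetime(2022, 1, 10, 6, tzinfo=UTC))
            for _ in range(300)
        ]
        events = detect_interactions(steps, smap)
        got = {(id(e.step), e.surface_id) for e in events}
        expected = set()
        for s in steps:
            (x0, y0), (x1, y1) = s.segment
            n = max(int(s.length_m / 0.01), 2)
            ts = np.linspace(0.0, 1.0, n)
            pts = shapely.points(x0 + ts * (x1 - x0), y0 + ts * (y1 - y0))
            for r in rects:
                if shapely.covers(r.geometry, pts).any():
                    expected.add((id(s), r.surface_id))
        assert got == expected


class TestAggregation:
    def test_daily_counts_zero_filled(self):
        d1, d2 = date(2022, 1, 10), date(2022, 1, 11)
        events = detect_interactions(
            [_step(100, 50, 100, 200), _step(200, 50, 200, 200)], _map(RUNWAY)
        )
        table = daily_counts(events, {"a": (d1, d2)})
        assert len(table) == 2
        assert table.loc[table["date"] == d1, "n_interactions"].item() == 2
        assert table.loc[table["date"] == d2, "n_interactions"].item() == 0

    def test_mean_daily_rate_matches_study_rates(self):
        totals = [2239, 1798, 164, 341, 29]
        days = [226, 195, 213, 217, 260]
        assert round(mean_daily_rate(totals, days), 1) == 4.3

    def test_no_events_rate_zero(self):
        assert mean_daily_rate([0, 0], [10, 20]) == 0.0

    def test_monthly_summary_mean_and_range(self):
        t_jan = datetime(2022, 1, 10, 6, tzinfo=UTC)
        steps = [
            _step(100, 50, 100, 200, t=t_jan, animal="a"),
            _step(200, 50, 200, 200, t=t_jan, animal="a"),
            _step(300, 50, 300, 200, t=t_jan, animal="b"),
        ]
        events = detect_interactions(steps, _map(RUNWAY))
        table = monthly_summary(events, n_animals=4)
        row = table[table["month"] == 1].iloc[0]
        assert row["total"] == 3
        assert row["mean"] == pytest.approx(3 / 4)
        assert (row["range_min"], row["range_max"]) == (0, 2)

    def test_monthly_exclusion(self):
        t_jul = datetime(2022, 7, 10, 6, tzinfo=UTC)
        events = detect_interactions([_step(100, 50, 100, 200, t=t_jul)], _map(RUNWAY))
        table = monthly_summary(events, n_animals=5, exclude_months=(7,))
        assert table.empty

    def test_invalid_n_animals(self):
        with pytest.raises(ValueError):
            monthly_summary([], n_animals=0)


class TestBreakdown:
    def test_percentages_from_study_counts(self):
        table = breakdown_from_counts({"runway": 1706, "taxiway": 2502, "connecting": 363})
        pct = dict(zip(table["key"], table["pct"]))
        assert round(pct["runway"], 1) == 37.3
        assert round(pct["taxiway"], 1) == 54.7
        assert table["pct"].sum() == pytest.approx(100.0)

    def test_single_category_is_100(self):
        events = detect_interactions([_step(100, 50, 100, 200)], _map(RUNWAY, TAXIWAY))
        out = category_breakdown(events)["by_category"]
        pct = dict(zip(out["key"], out["pct"]))
        assert pct["runway"] == 100.0 and pct["taxiway"] == 0.0

    def test_per_label_share(self):
        table = breakdown_from_counts({"16-34": 1564, "10L-28R": 116, "10R-28L": 26})
        pct = dict(zip(table["key"], table["pct"]))
        assert round(pct["16-34"], 1) == 91.7


class TestExtrapolation:
    def test_population_scaling(self):
        out = population_extrapolation(4.3, 118)
        assert out.interactions_per_day == pytest.approx(507.4)

    def test_zero_rate(self):
        assert population_extrapolation(0.0, 118).interactions_per_day == 0.0

    def test_occupancy_seconds(self):
        out = population_extrapolation(1.0, 10, mean_event_duration_s=60.0)
        assert out.occupancy_s_per_day == pytest.approx(600.0)
        assert out.occupancy_h_per_day == pytest.approx(1 / 6)

    def test_trimmed_mean_from_summary(self):
        # 31 timed tarmac visits averaging 67 s, two long runway rests removed
        assert trimmed_mean_excluding(31, 67.0, (971.0, 553.0)) == pytest.approx(
            553.0 / 29.0
        )

    def test_conservation_totals(self):
        steps = [
            _step(100, 50, 100, 200, animal="a"),
            _step(100, -10, 100, 200, animal="b"),
        ]
        events = detect_interactions(steps, _map(RUNWAY, TAXIWAY))
        cat = category_breakdown(events)["by_category"]
        assert cat["count"].sum() == len(events)
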