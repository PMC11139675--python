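"""End-to-end orchestration: ingest → QC → interactions → solar offsets →
movement metrics → home ranges, with report tables and consistency checks.

The report tables mirror the study-summary layout: a per-animal deployment
table (fixes, interactions, % of fixes interacting), a monthly interaction
table (total / mean / range) and a home-range table (area plus habitat
composition)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interactions as ia
from . import movement as mv
from .airfield_geometry import SurfaceMap, load_surface_map
from .home_range import (
    HomeRange,
    contour_home_range,
    habitat_composition,
    href_bandwidth,
    kernel_ud,
)
from .projection import TransverseMercator
from .solar import SunTimeSource, clock_histogram, seasonal_offset_comparison, offsets_for_events, season_of
from .trajectory_io import build_steps, filter_fixes, read_gps_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gps_csv: str
    map_geojson: str
    out_dir: str
    site_lat: float
    site_lon: float
    tz: str = "Europe/Dublin"
    max_accuracy_m: float = 30.0
    burn_in_days: int = 5
    exclude_months: tuple[int, ...] = ()
    kud_level: float = 0.95
    clock_bin_h: int = 3
    sun_lookup_csv: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["exclude_months"] = tuple(data.get("exclude_months", ()))
        return cls(**data)


@dataclass
class PipelineResult:
    table1: pd.DataFrame                 # per-animal deployment summary
    table2: pd.DataFrame                 # monthly interaction summary
    table3: pd.DataFrame                 # home range + habitat composition
    daily_counts: pd.DataFrame
    daily_distance: pd.DataFrame
    monthly_cumulative: pd.DataFrame
    step_summary: pd.DataFrame
    clock_shares: dict
    events: list
    home_ranges: list[HomeRange]
    reports: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every analysis stage and write report CSV/JSON files.

    Any stage that cannot run on the supplied data for structural reasons
    (e.g. a seasonal test with a single season) is recorded in
    ``reports`` with a reason instead of aborting the run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proj = TransverseMercator(cfg.site_lon, cfg.site_lat)

    # ingest + QC
    trajectories = read_gps_table(cfg.gps_csv, projection=proj, tz=cfg.tz)
    if not trajectories:
        raise RuntimeError("ingest stage: no trajectories in GPS table")
    filter_log = {}
    filtered = []
    for traj in trajectories:
        res = filter_fixes(traj, cfg.max_accuracy_m, cfg.burn_in_days)
        filter_log[traj.animal_id] = {
            "n_raw": len(traj),
            "n_removed_accuracy": res.n_removed_accuracy,
            "n_removed_burn_in": res.n_removed_burn_in,
            "n_kept": len(res.trajectory),
        }
        if len(res.trajectory) >= 2:
            filtered.append(res.trajectory)
    if not filtered:
        raise RuntimeError("filter stage: no trajectory with >=2 fixes retained")

    smap = load_surface_map(cfg.map_geojson)
    steps_by_animal = {t.animal_id: build_steps(t) for t in filtered}
    all_steps = [s for ss in steps_by_animal.values() for s in ss]

    # interactions
    events = ia.detect_interactions(all_steps, smap)
    deployments = {
        t.animal_id: (t.fixes[0].t_local.date(), t.fixes[-1].t_local.date())
        for t in filtered
    }
    daily = ia.daily_counts(events, deployments)
    n_animals = len(filtered)
    table2 = ia.monthly_summary(events, n_animals, exclude_months=cfg.exclude_months)
    breakdown = ia.category_breakdown(events)

    # per-animal deployment summary
    rows = []
    for t in filtered:
        n_events = sum(1 for e in events if e.animal_id == t.animal_id)
        n_fixes = len(t)
        start, end = deployments[t.animal_id]
        rows.append(
            {
                "animal_id": t.animal_id,
                "start": start,
                "end": end,
                "days": max((end - start).days, 1),
                "n_fixes": n_fixes,
                "n_interactions": n_events,
                "pct_fixes_interacting": round(100.0 * n_events / n_fixes, 1),
            }
        )
    table1 = pd.DataFrame(rows)

    # solar offsets and clock histograms
    sun = SunTimeSource(cfg.site_lat, cfg.site_lon, cfg.tz, lookup_csv=cfg.sun_lookup_csv)
    event_times = [e.t_event for e in events]
    offsets = offsets_for_events(event_times, sun)
    by_season: dict[str, list[float]] = {}
    for e, o in zip(events, offsets):
        by_season.setdefault(e.season, []).append(o.offset_h)
    reports: dict = {"category_breakdown": {
        "by_category": breakdown["by_category"].to_dict("records"),
        "by_label": {k: v.to_dict("records") for k, v in breakdown["by_label"].items()},
    }}
    try:
        reports["seasonal_offsets"] = seasonal_offset_comparison(by_season).to_dict()
    except ValueError as exc:
        reports["seasonal_offsets"] = {"skipped": str(exc)}
    clock_shares = {
        "overall": clock_histogram(event_times, cfg.clock_bin_h).tolist(),
    }
    for season in sorted({e.season for e in events}):
        clock_shares[f"season:{season}"] = clock_histogram(
            [e.t_event for e in events if e.season == season], cfg.clock_bin_h
        ).tolist()
    for cat in ("runway", "taxiway", "connecting"):
        sub = [e.t_event for e in events if e.category == cat]
        if sub:
            clock_shares[f"category:{cat}"] = clock_histogram(sub, cfg.clock_bin_h).tolist()

    # movement metrics
    daily_dist = mv.daily_distance(all_steps, deployments)
    monthly_cum = mv.monthly_cumulative(
        daily_dist, deployments, full_months_only=True,
        keep_months=_first_month_exceptions(deployments),
    )
    try:
        reports["monthly_distance_test"] = mv.monthly_distance_test(
            daily_dist, exclude_months=cfg.exclude_months
        ).to_dict()
    except ValueError as exc:
        reports["monthly_distance_test"] = {"skipped": str(exc)}
    step_summary = mv.step_length_summary(all_steps)

    # home ranges
    home_ranges: list[HomeRange] = []
    hr_rows = []
    for t in filtered:
        pts = t.xy()
        if len(pts) < 10:
            logger.warning("%s: too few fixes for a home range", t.animal_id)
            continue
        h = href_bandwidth(pts)
        ud = kernel_ud(pts, h, animal_id=t.animal_id)
        hr = contour_home_range(ud, level=cfg.kud_level)
        props = habitat_composition(hr, smap)
        home_ranges.append(hr)
        row = {"animal_id": t.animal_id, "area_ha": round(hr.area_ha, 1),
               "bandwidth_m": h}
        row.update({f"prop_{k}": v for k, v in sorted(props.items())})
        hr_rows.append(row)
    table3 = pd.DataFrame(hr_rows)

    result = PipelineResult(
        table1=table1, table2=table2, table3=table3,
        daily_counts=daily, daily_distance=daily_dist,
        monthly_cumulative=monthly_cum, step_summary=step_summary,
        clock_shares=clock_shares, events=events, home_ranges=home_ranges,
        reports=reports, filter_log=filter_log,
    )
    _write_outputs(result, out)
    return result


def _first_month_exceptions(deployments) -> tuple[tuple[int, int], ...]:
    """Retain each collar's shared first partial month (study convention:
    a first month when all collars started on the same mid-month date)."""
    starts = {start for start, _ in deployments.values()}
    if len(starts) == 1:
        s = next(iter(starts))
        if s.day != 1:
            return ((s.year, s.month),)
    return ()


def _write_outputs(result: PipelineResult, out: Path) -> None:
    result.table1.to_csv(out / "table1_deployment.csv", index=False)
    result.table2.to_csv(out / "table2_monthly_interactions.csv", index=False)
    result.table3.to_csv(out / "table3_home_ranges.csv", index=False)
    result.daily_counts.to_csv(out / "daily_interaction_counts.csv", index=False)
    result.daily_distance.to_csv(out / "daily_distance_km.csv", index=False)
    result.monthly_cumulative.to_csv(out / "monthly_cumulative_km.csv", index=False)
    result.step_summary.to_csv(out / "step_length_summary.csv", index=False)
    ia.events_to_frame(result.events).to_csv(out / "interaction_events.csv", index=False)
    payload = {
        "reports": result.reports,
        "clock_shares": result.clock_shares,
        "filter_log": result.filter_log,
        "consistency": report_consistency_check(result),
    }
    (out / "reports.json").write_text(json.dumps(payload, indent=2, default=str))


def report_consistency_check(result: PipelineResult) -> list[dict]:
    """Arithmetic identities every internally consistent report satisfies.

    Returns one record per check with a pass flag — failures are data, not
    exceptions.
    """
    checks: list[dict] = []

    def add(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    t1 = result.table1
    if len(t1):
        total_t1 = int(t1["n_interactions"].sum())
        n_events = len(result.events)
        add("grand_total_equals_sum_over_animals", total_t1 == n_events,
            f"{total_t1} vs {n_events}")
        expect_pct = (100.0 * t1["n_interactions"] / t1["n_fixes"]).round(1)
        add("pct_column_matches_counts",
            bool(np.allclose(expect_pct, t1["pct_fixes_interacting"])),
            "pct = interactions / fixes x 100, 1 dp")
    t2 = result.table2
    if len(t2):
        n_animals = len(t1)
        add("monthly_mean_equals_total_over_animals",
            bool(np.allclose(t2["mean"], t2["total"] / n_animals)),
            f"n_animals={n_animals}")
        excluded = {
            pd.Timestamp(d).month
            for d in result.daily_counts["date"]
        } - set(t2["month"])
        add("monthly_totals_cover_event_months",
            int(t2["total"].sum())
            == sum(1 for e in result.events if e.month in set(t2["month"])),
            f"months excluded from table: {sorted(excluded)}")
    cat = result.reports.get("category_breakdown", {})
    by_cat = cat.get("by_category", [])
    if by_cat:
        total = sum(r["count"] for r in by_cat)
        add("category_counts_sum_to_total", total == len(result.events),
            f"{total} vs {len(result.events)}")
        pct_sum = sum(r["pct"] for r in by_cat)
        add("category_percentages_sum_to_100",
            total == 0 or abs(pct_sum - 100.0) < 1e-6, f"sum={pct_sum:.6f}")
    if len(t1):
        rates = t1["n_interactions"] / t1["days"]
        add("mean_daily_rate_finite", bool(np.isfinite(rates.mean())),
            f"mean rate {rates.mean():.2f}/day")
    t3 = result.table3
    if len(t3):
        add("home_range_areas_positive", bool((t3["area_ha"] > 0).all()))
        prop_cols = [c for c in t3.columns if c.startswith("prop_")]
        sums = t3[prop_cols].sum(axis=1)
        add("habitat_proportions_sum_to_1",
            bool(np.allclose(sums, 1.0, atol=1e-6)),
            f"row sums {sums.round(6).tolist()}")
    return checks
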