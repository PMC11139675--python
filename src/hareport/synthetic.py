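"""Synthetic airfield and two-state hare movement simulation.

Provides a parametric airfield map (runways ~60 m wide, parallel taxiways
~35 m, connecting strips, grassland islands and marginal apron / built /
service surfaces) and a continuous-time movement simulator that emulates
the collar sampling design of an airside tracking study:

* two behavioural states — *active* (correlated random walk attracted to a
  home centre) and *resting* (stationary) — switching with a crepuscular
  activity probability anchored to sunrise and sunset;
* a state-dependent fix schedule (a fix every 10 min when active, every
  6 h at rest, mimicking accelerometer-informed collars);
* per-fix GPS noise whose magnitude scales with a drawn horizontal-accuracy
  value, with a configurable fraction of fixes worse than the 30 m QC
  cutoff.

The simulator records ground truth — the dense true path, the state
sequence, every true tarmac-crossing interval and the true daily path
length — so each pipeline stage can be tested against an oracle without
any field data.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_t, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .airfield_geometry import (
    SurfaceMap,
    SurfacePolygon,
    dump_surface_map,
    tarmacked_subset,
    validate_surface_map,
)
from .projection import TransverseMercator
from .solar import SunTimeSource

SITE_LAT, SITE_LON = 53.4264, -6.2499  # reference site (Dublin Airport)


# --- airfield ------------------------------------------------------------

@dataclass(frozen=True)
class AirfieldLayout:
    """Parametric rectangle layout, planar metres, site-centred frame."""

    runway_length_m: float = 3000.0
    runway_width_m: float = 60.0
    taxiway_width_m: float = 35.0
    connector_width_m: float = 20.0
    boundary_halfwidth_m: float = 2000.0
    boundary_halfheight_m: float = 1500.0


def make_airfield(layout: AirfieldLayout | None = None, seed: int = 0) -> SurfaceMap:
    """Build the default two-runway synthetic airfield.

    Runway N (semi-operational) with its inactive parallel taxiway lies in
    the north; runway S (active) with an active taxiway in the south.
    Three connecting strips abut each runway/taxiway pair (no tarmac
    overlap). Grassland islands fill the gaps; apron, built land, a service
    road and a small unknown surface sit at the margins. The layout is
    fully deterministic; ``seed`` is accepted for interface symmetry.
    """
    lo = layout or AirfieldLayout()
    hl = lo.runway_length_m / 2.0
    polys: list[SurfacePolygon] = []

    def add(sid, geom, cls, status="not_applicable", label=""):
        polys.append(SurfacePolygon(sid, geom, cls, status, label))

    # north pair: semi-operational runway, inactive taxiway
    add("RWY-N", box(-hl, 270, hl, 270 + lo.runway_width_m),
        "tarmac_runway", "semi_operational", "RWY-N")
    add("TWY-N", box(-hl, 150, hl, 150 + lo.taxiway_width_m),
        "tarmac_taxiway", "inactive", "TWY-N")
    # south pair: active runway and taxiway
    add("RWY-S", box(-hl, -800, hl, -800 + lo.runway_width_m),
        "tarmac_runway", "active", "RWY-S")
    add("TWY-S", box(-hl, -920, hl, -920 + lo.taxiway_width_m),
        "tarmac_taxiway", "active", "TWY-S")
    # connecting strips abut runway and taxiway edges exactly
    w = lo.connector_width_m / 2.0
    for i, cx in enumerate((-1000.0, 0.0, 1000.0)):
        add(f"CON-N{i}", box(cx - w, 185, cx + w, 270),
            "tarmac_connecting", "semi_operational", f"CON-N{i}")
        add(f"CON-S{i}", box(cx - w, -885, cx + w, -800),
            "tarmac_connecting", "active", f"CON-S{i}")

    # grassland islands between and around the tarmac
    grass = [
        box(-hl, 360, hl, 1300),        # north of runway N
        box(-hl, -700, hl, 120),        # central belt
        box(-hl, -1400, hl, -950),      # south of taxiway S
        box(hl + 100, -1400, lo.boundary_halfwidth_m - 50, 1300),  # east
        box(-lo.boundary_halfwidth_m + 50, -1400, -hl - 100, 1300),  # west
    ]
    for i, g in enumerate(grass):
        add(f"GRASS-{i}", g, "grassland")
    add("APRON-0", box(-hl, 1320, -hl + 600, 1450), "apron")
    add("BUILT-0", box(-hl + 700, 1320, -hl + 1200, 1450), "built_land")
    add("SVC-0", box(-hl, 130, hl, 145), "service_road")
    add("UNK-0", box(hl - 300, 1320, hl, 1400), "unknown")

    boundary = box(
        -lo.boundary_halfwidth_m, -lo.boundary_halfheight_m,
        lo.boundary_halfwidth_m, lo.boundary_halfheight_m,
    )
    return validate_surface_map(SurfaceMap(polygons=polys, boundary=boundary))


# --- simulation config ---------------------------------------------------

@dataclass
class SimConfig:
    seed: int = 0
    n_animals: int = 5
    start: date_t = date_t(2021, 12, 5)
    n_days: int = 30
    site_lat: float = SITE_LAT
    site_lon: float = SITE_LON
    tz: str = "Europe/Dublin"
    #: per-animal home centres, planar m; auto-placed if None
    home_centres: list[tuple[float, float]] | None = None
    home_attraction: float = 0.012      # per-minute pull toward home (fraction of offset)
    speed_mean_m_min: float = 8.0       # active-state speed
    speed_shape: float = 4.0            # gamma shape of per-minute speed
    turning_kappa: float | None = 4.0   # von Mises heading persistence; None = ballistic
    activity_baseline: float = 0.10     # activity probability away from twilight
    crepuscular_peak: float = 0.75      # added activity probability at sun events
    peak_width_h: float = 1.5
    mean_active_bout_min: float = 60.0
    mean_rest_bout_min: float = 180.0
    fix_interval_active_min: int = 10
    fix_interval_rest_min: int = 360
    sim_step_min: int = 1
    accuracy_mean_m: float = 7.5        # typical horizontal accuracy
    frac_accuracy_over_30: float = 0.02
    noise_per_accuracy: float = 0.5     # GPS error sd = accuracy × this

    def __post_init__(self) -> None:
        if self.n_days <= 0 or self.n_animals <= 0:
            raise ValueError("n_days and n_animals must be positive")
        if not 0.0 <= self.frac_accuracy_over_30 <= 1.0:
            raise ValueError("frac_accuracy_over_30 must lie in [0, 1]")
        for v in (self.fix_interval_active_min, self.fix_interval_rest_min,
                  self.sim_step_min, self.mean_active_bout_min, self.mean_rest_bout_min):
            if v <= 0:
                raise ValueError("intervals and bout lengths must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    paths: dict[str, pd.DataFrame]        # animal -> t_utc, x, y, active
    crossings: pd.DataFrame               # animal_id, surface_id, t_entry, t_exit
    daily_path_km: pd.DataFrame           # animal_id, date(local), true_km

    def crossings_for(self, animal_id: str) -> pd.DataFrame:
        return self.crossings[self.crossings["animal_id"] == animal_id]


def _activity_probability(t_local: datetime, sun, cfg: SimConfig) -> float:
    h = t_local.hour + t_local.minute / 60.0
    rise = sun.sunrise_local.hour + sun.sunrise_local.minute / 60.0
    sset = sun.sunset_local.hour + sun.sunset_local.minute / 60.0
    p = cfg.activity_baseline
    for anchor in (rise, sset):
        d = min(abs(h - anchor), 24.0 - abs(h - anchor))  # circular hour distance
        p += cfg.crepuscular_peak * np.exp(-(d**2) / (2.0 * cfg.peak_width_h**2))
    return min(p, 0.95)


def _default_home_centres(n: int) -> list[tuple[float, float]]:
    """Two animals beside the northern (semi-operational) tarmac, the rest
    in grassland several hundred metres from any tarmac edge."""
    near = [(-400.0, 500.0), (500.0, 10.0)]
    far = [(900.0, -430.0), (-700.0, -440.0), (200.0, -425.0),
           (1400.0, -450.0), (-1200.0, -500.0)]
    if n <= 2:
        return near[:n]
    return near + far[: n - 2]


def simulate_hares(
    smap: SurfaceMap, cfg: SimConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate collared hares on the airfield.

    Returns a fix table in the CSV dialect ``trajectory_io.read_gps_table``
    expects (animal_id, timestamp, lon, lat, h_accuracy) and the
    :class:`SyntheticTruth` log. Deterministic for a given config/seed.
    """
    proj = TransverseMercator(cfg.site_lon, cfg.site_lat)
    sun = SunTimeSource(cfg.site_lat, cfg.site_lon, cfg.tz)
    centres = cfg.home_centres or _default_home_centres(cfg.n_animals)
    if len(centres) < cfg.n_animals:
        raise ValueError("need one home centre per animal")
    tarmac = tarmacked_subset(smap).polygons

    t0 = datetime(cfg.start.year, cfg.start.month, cfg.start.day, tzinfo=timezone.utc)
    n_steps = cfg.n_days * 24 * 60 // cfg.sim_step_min
    dt_min = float(cfg.sim_step_min)

    fix_rows = []
    paths: dict[str, pd.DataFrame] = {}
    crossing_rows = []
    daily_rows = []

    # local civil time per simulation minute (shared across animals)
    times_utc = [t0 + timedelta(minutes=i * dt_min) for i in range(n_steps + 1)]
    from .trajectory_io import to_local_time

    times_local = [to_local_time(t, cfg.tz) for t in times_utc]
    p_active = np.array(
        [_activity_probability(tl, sun(tl.date()), cfg) for tl in times_local]
    )

    for a_idx in range(cfg.n_animals):
        animal_id = f"H{a_idx + 1:02d}"
        rng = np.random.default_rng([cfg.seed, a_idx])
        home = np.array(centres[a_idx], dtype=float)
        pos = home.copy()
        heading = rng.uniform(0.0, 2.0 * np.pi)
        active = rng.random() < p_active[0]

        xs = np.empty(n_steps + 1)
        ys = np.empty(n_steps + 1)
        states = np.empty(n_steps + 1, dtype=bool)
        xs[0], ys[0] = pos
        states[0] = active

        # pre-drawn randomness for speed and turning
        speeds = rng.gamma(cfg.speed_shape, cfg.speed_mean_m_min / cfg.speed_shape,
                           size=n_steps) * dt_min
        if cfg.turning_kappa is not None:
            turns = rng.vonmises(0.0, cfg.turning_kappa, size=n_steps)
        else:
            turns = np.zeros(n_steps)
        u_switch = rng.random(size=(n_steps, 2))

        for i in range(n_steps):
            # state redraw at ~1/mean_bout hazard of the current state
            bout = cfg.mean_active_bout_min if active else cfg.mean_rest_bout_min
            if u_switch[i, 0] < dt_min / bout:
                active = u_switch[i, 1] < p_active[i]
            if active:
                heading = heading + turns[i]
                step = speeds[i] * np.array([np.cos(heading), np.sin(heading)])
                pull = cfg.home_attraction * dt_min * (home - pos)
                pos = pos + step + pull
            xs[i + 1], ys[i + 1] = pos
            states[i + 1] = active

        paths[animal_id] = pd.DataFrame(
            {"t_utc": times_utc, "x": xs, "y": ys, "active": states}
        )

        # ground-truth crossings: runs of dense path points inside each tarmac polygon
        pts = shapely.points(xs, ys)
        for poly in tarmac:
            inside = shapely.covers(poly.geometry, pts)
            if not inside.any():
                continue
            d = np.diff(inside.astype(np.int8))
            entries = list(np.flatnonzero(d == 1) + 1)
            exits = list(np.flatnonzero(d == -1))
            if inside[0]:
                entries.insert(0, 0)
            if inside[-1]:
                exits.append(n_steps)
            for e_i, x_i in zip(entries, exits):
                crossing_rows.append(
                    {"animal_id": animal_id, "surface_id": poly.surface_id,
                     "t_entry": times_utc[e_i], "t_exit": times_utc[x_i]}
                )

        # true daily path lengths (local dates)
        seg_len = np.hypot(np.diff(xs), np.diff(ys))
        dates = [times_local[i].date() for i in range(n_steps)]
        daily = pd.DataFrame({"date": dates, "m": seg_len}).groupby("date")["m"].sum()
        for d, m in daily.items():
            daily_rows.append({"animal_id": animal_id, "date": d, "true_km": m / 1000.0})

        # sample fixes per the state-dependent schedule: a fix fires once the
        # time since the last fix reaches the current state's interval, so
        # the 10-min schedule resumes promptly when activity restarts
        last_fix = -np.inf
        for i in range(n_steps + 1):
            t_min = i * dt_min
            interval = (
                cfg.fix_interval_active_min if states[i] else cfg.fix_interval_rest_min
            )
            if t_min - last_fix < interval:
                continue
            bad = rng.random() < cfg.frac_accuracy_over_30
            if bad:
                accuracy = rng.uniform(31.0, 80.0)
            else:
                accuracy = min(rng.gamma(4.0, cfg.accuracy_mean_m / 4.0), 29.5)
            err = rng.normal(0.0, cfg.noise_per_accuracy * accuracy, size=2)
            lon, lat = proj.inverse(xs[i] + err[0], ys[i] + err[1])
            fix_rows.append(
                {
                    "animal_id": animal_id,
                    "timestamp": times_utc[i].strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "lon": float(lon),
                    "lat": float(lat),
                    "h_accuracy": round(float(accuracy), 1),
                }
            )
            last_fix = t_min

    fixes = pd.DataFrame(fix_rows, columns=["animal_id", "timestamp", "lon", "lat", "h_accuracy"])
    truth = SyntheticTruth(
        paths=paths,
        crossings=pd.DataFrame(
            crossing_rows, columns=["animal_id", "surface_id", "t_entry", "t_exit"]
        ),
        daily_path_km=pd.DataFrame(daily_rows, columns=["animal_id", "date", "true_km"]),
    )
    return fixes, truth


@dataclass
class ScenarioBundle:
    fixes: pd.DataFrame
    truth: SyntheticTruth
    surface_map: SurfaceMap
    config: SimConfig
    projection: TransverseMercator


def scenario_study_like(seed: int = 42, n_days: int = 30) -> ScenarioBundle:
    """Desk-scale analogue of the collar study: five animals, two beside the
    semi-operational northern tarmac and three in distant grassland, over a
    ~month of simulated tracking starting in early December."""
    smap = make_airfield()
    cfg = SimConfig(seed=seed, n_days=n_days)
    fixes, truth = simulate_hares(smap, cfg)
    return ScenarioBundle(
        fixes=fixes,
        truth=truth,
        surface_map=smap,
        config=cfg,
        projection=TransverseMercator(cfg.site_lon, cfg.site_lat),
    )


def write_scenario(bundle: ScenarioBundle, out_dir) -> dict[str, str]:
    """Write fixes CSV, airfield GeoJSON and truth logs to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixes": str(out / "fixes.csv"),
        "airfield": str(out / "airfield.geojson"),
        "truth_crossings": str(out / "truth_crossings.csv"),
        "truth_daily": str(out / "truth_daily_km.csv"),
    }
    bundle.fixes.to_csv(paths["fixes"], index=False)
    dump_surface_map(bundle.surface_map, paths["airfield"])
    bundle.truth.crossings.to_csv(paths["truth_crossings"], index=False)
    bundle.truth.daily_path_km.to_csv(paths["truth_daily"], index=False)
    return paths
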