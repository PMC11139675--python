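"""GPS fix ingest, quality control and step construction.

Reads Movebank-style relocation tables (one row per GPS fix), applies the
standard collar-study quality filters — a horizontal-accuracy cutoff and a
post-capture burn-in window — converts timestamps to DST-aware local time,
and turns each animal's fix sequence into straight-line movement steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from zoneinfo import ZoneInfo, ZoneInfoNotFoundError

import numpy as np
import pandas as pd

from .projection import TransverseMercator

logger = logging.getLogger(__name__)

#: default CSV column names (Movebank-flavoured); override via ``column_map``
DEFAULT_COLUMNS = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "h_accuracy": "h_accuracy",
}


@dataclass(frozen=True)
class Fix:
    """A single GPS relocation."""

    animal_id: str
    t_utc: datetime
    t_local: datetime
    x: float  # planar easting, m
    y: float  # planar northing, m
    lon: float
    lat: float
    h_accuracy: float | None  # horizontal accuracy, m; None if not reported


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal plus its deployment window."""

    animal_id: str
    fixes: list[Fix]
    deploy_start: datetime | None = None
    deploy_end: datetime | None = None

    def __post_init__(self) -> None:
        if self.fixes and self.deploy_start is None:
            self.deploy_start = self.fixes[0].t_utc
        if self.fixes and self.deploy_end is None:
            self.deploy_end = self.fixes[-1].t_utc

    def __len__(self) -> int:
        return len(self.fixes)

    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in metres."""
        return np.array([[f.x, f.y] for f in self.fixes], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class Step:
    """The straight segment between two consecutive fixes.

    ``t_event`` anchors the step in time at the earlier fix; ``degenerate``
    marks zero-length steps (identical coordinates), which are retained for
    bookkeeping but excluded from geometric intersection tests.
    """

    animal_id: str
    fix_a: Fix
    fix_b: Fix
    length_m: float
    duration_s: float
    degenerate: bool
    long_gap: bool = False

    @property
    def t_event(self) -> datetime:
        return self.fix_a.t_local

    @property
    def segment(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((self.fix_a.x, self.fix_a.y), (self.fix_b.x, self.fix_b.y))


@dataclass
class FilterResult:
    trajectory: Trajectory
    n_removed_accuracy: int = 0
    n_removed_burn_in: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_removed_accuracy + self.n_removed_burn_in


def to_local_time(t_utc: datetime, zone: str) -> datetime:
    """Convert a UTC instant to DST-aware civil time in an IANA zone."""
    try:
        tz = ZoneInfo(zone)
    except (ZoneInfoNotFoundError, KeyError) as exc:
        raise ValueError(f"unknown time zone: {zone!r}") from exc
    if t_utc.tzinfo is None:
        t_utc = t_utc.replace(tzinfo=timezone.utc)
    return t_utc.astimezone(tz)


def read_gps_table(
    path,
    projection: TransverseMercator | None = None,
    column_map: dict[str, str] | None = None,
    tz: str = "Europe/Dublin",
) -> list[Trajectory]:
    """Read a GPS fix CSV into one :class:`Trajectory` per animal.

    The CSV must carry an animal id, an ISO-8601 UTC timestamp, longitude,
    latitude and horizontal accuracy (metres; may be empty). Rows with
    unparseable timestamps are dropped and counted in the log. If no
    ``projection`` is given, a transverse-Mercator frame centred on the data
    bounding box is constructed.

    Returns trajectories sorted by animal id, fixes sorted by time.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype={cols["animal_id"]: str})
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"GPS table missing mandatory column(s): {missing}")
    if df.empty:
        return []

    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce", utc=True)
    n_bad = int(ts.isna().sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable timestamps", n_bad)
        df = df[ts.notna()]
        ts = ts[ts.notna()]
    df = df.assign(_t_utc=ts).sort_values([cols["animal_id"], "_t_utc"])

    if projection is None:
        projection = TransverseMercator.for_points(
            df[cols["lon"]].to_numpy(), df[cols["lat"]].to_numpy()
        )

    trajectories: list[Trajectory] = []
    for animal_id, grp in df.groupby(cols["animal_id"], sort=True):
        x, y = projection.forward(
            grp[cols["lon"]].to_numpy(), grp[cols["lat"]].to_numpy()
        )
        acc = grp[cols["h_accuracy"]].to_numpy(dtype=float)
        fixes = []
        for i, (t, lon, lat) in enumerate(
            zip(grp["_t_utc"], grp[cols["lon"]], grp[cols["lat"]])
        ):
            t_utc = t.to_pydatetime()
            a = float(acc[i])
            fixes.append(
                Fix(
                    animal_id=str(animal_id),
                    t_utc=t_utc,
                    t_local=to_local_time(t_utc, tz),
                    x=float(x[i]),
                    y=float(y[i]),
                    lon=float(lon),
                    lat=float(lat),
                    h_accuracy=None if np.isnan(a) else a,
                )
            )
        trajectories.append(Trajectory(animal_id=str(animal_id), fixes=fixes))
    return trajectories


def filter_fixes(
    traj: Trajectory,
    max_accuracy_m: float = 30.0,
    burn_in_days: int = 5,
) -> FilterResult:
    """Apply the accuracy cutoff and post-capture burn-in window.

    Fixes with horizontal accuracy *strictly greater than* ``max_accuracy_m``
    are removed (a fix at exactly the cutoff is retained); fixes with a
    missing accuracy value are retained and logged. Fixes earlier than
    ``deploy_start + burn_in_days × 24 h`` are removed. Idempotent.
    """
    if max_accuracy_m <= 0:
        raise ValueError("max_accuracy_m must be positive")
    result = FilterResult(trajectory=Trajectory(traj.animal_id, [], traj.deploy_start, traj.deploy_end))
    cutoff_t = None
    if traj.deploy_start is not None:
        cutoff_t = traj.deploy_start + timedelta(days=burn_in_days)

    n_missing_acc = 0
    kept: list[Fix] = []
    for f in traj.fixes:
        if f.h_accuracy is not None and f.h_accuracy > max_accuracy_m:
            result.n_removed_accuracy += 1
            continue
        if f.h_accuracy is None:
            n_missing_acc += 1
        if cutoff_t is not None and f.t_utc < cutoff_t:
            result.n_removed_burn_in += 1
            continue
        kept.append(f)
    if n_missing_acc:
        msg = f"{n_missing_acc} fixes retained with missing accuracy value"
        result.notes.append(msg)
        logger.info("%s: %s", traj.animal_id, msg)
    if not kept:
        msg = "all fixes removed by quality filters"
        result.notes.append(msg)
        logger.warning("%s: %s", traj.animal_id, msg)
    result.trajectory = Trajectory(
        traj.animal_id, kept, traj.deploy_start, traj.deploy_end
    )
    return result


def build_steps(traj: Trajectory, long_gap_s: float | None = None) -> list[Step]:
    """Connect consecutive fixes into straight-line steps.

    A trajectory of n fixes yields n−1 steps. Zero-length steps are kept but
    flagged ``degenerate``. If ``long_gap_s`` is given, steps whose duration
    exceeds it (e.g. spanning the 6-h resting schedule) are annotated
    ``long_gap`` — annotated only, never dropped.
    """
    steps: list[Step] = []
    for a, b in zip(traj.fixes, traj.fixes[1:]):
        length = float(np.hypot(b.x - a.x, b.y - a.y))
        duration = (b.t_utc - a.t_utc).total_seconds()
        steps.append(
            Step(
                animal_id=traj.animal_id,
                fix_a=a,
                fix_b=b,
                length_m=length,
                duration_s=duration,
                degenerate=(length == 0.0),
                long_gap=(long_gap_s is not None and duration > long_gap_s),
            )
        )
    return steps


def steps_to_frame(steps: list[Step]) -> pd.DataFrame:
    """Tabular view of a step list (one row per step)."""
    return pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in steps],
            "t_event": [s.t_event for s in steps],
            "length_m": [s.length_m for s in steps],
            "duration_s": [s.duration_s for s in steps],
            "degenerate": [s.degenerate for s in steps],
        }
    )
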