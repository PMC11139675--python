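"""Tarmacked-area interaction detection and aggregation.

An *interaction* is an intersection between the straight-line path joining
two consecutive GPS fixes and a tarmacked surface (runway, taxiway or
connecting strip). The counting unit is the (step, polygon) pair: a step
that enters, leaves and re-enters the same polygon counts once, while a
single step crossing a runway and then its parallel taxiway counts twice —
each intersected surface is an independent strike-risk event. Boundary
grazing (touching an edge at a point) counts.

Crossings that start and end entirely between two fixes (out-and-back
faster than the fix schedule) are undetectable from the sampled path; the
counts here are therefore conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_t, timedelta

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import LineString

from .airfield_geometry import SurfaceMap, tarmacked_subset
from .solar import season_of
from .trajectory_io import Step

TARMAC_CATEGORY = {
    "tarmac_runway": "runway",
    "tarmac_taxiway": "taxiway",
    "tarmac_connecting": "connecting",
}


@dataclass(frozen=True)
class InteractionEvent:
    animal_id: str
    step: Step
    surface_id: str
    habitat_class: str
    activity_status: str
    label: str

    @property
    def t_event(self):
        return self.step.t_event

    @property
    def date(self) -> date_t:
        return self.step.t_event.date()

    @property
    def month(self) -> int:
        return self.step.t_event.month

    @property
    def season(self) -> str:
        return season_of(self.date)

    @property
    def category(self) -> str:
        return TARMAC_CATEGORY[self.habitat_class]


def detect_interactions(steps: list[Step], smap: SurfaceMap) -> list[InteractionEvent]:
    """One event per (non-degenerate step, intersected tarmacked polygon).

    Events are returned in deterministic order: (animal id, event time,
    surface id). Degenerate (zero-length) steps never intersect.
    """
    tarmac = tarmacked_subset(smap).polygons
    if not tarmac:
        raise ValueError("surface map contains no tarmacked polygons")
    tree = STRtree([p.geometry for p in tarmac])
    events: list[InteractionEvent] = []
    for step in steps:
        if step.degenerate:
            continue
        seg = LineString(step.segment)
        for idx in tree.query(seg):
            poly = tarmac[int(idx)]
            if seg.intersects(poly.geometry):
                events.append(
                    InteractionEvent(
                        animal_id=step.animal_id,
                        step=step,
                        surface_id=poly.surface_id,
                        habitat_class=poly.habitat_class,
                        activity_status=poly.activity_status,
                        label=poly.label,
                    )
                )
    events.sort(key=lambda e: (e.animal_id, e.t_event, e.surface_id))
    return events


def events_to_frame(events: list[InteractionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [e.animal_id for e in events],
            "t_local": [e.t_event for e in events],
            "date": [e.date for e in events],
            "month": [e.month for e in events],
            "season": [e.season for e in events],
            "surface_id": [e.surface_id for e in events],
            "habitat_class": [e.habitat_class for e in events],
            "category": [e.category for e in events],
            "activity_status": [e.activity_status for e in events],
            "label": [e.label for e in events],
        }
    )


def daily_counts(
    events: list[InteractionEvent],
    deployments: dict[str, tuple[date_t, date_t]],
) -> pd.DataFrame:
    """Zero-filled per-animal per-day event counts.

    ``deployments`` maps animal id to its (first, last) local observation
    date; every date in that window appears in the output, with 0 where no
    event was recorded.
    """
    rows = []
    counts: dict[tuple[str, date_t], int] = {}
    for e in events:
        counts[(e.animal_id, e.date)] = counts.get((e.animal_id, e.date), 0) + 1
    for animal_id, (start, end) in sorted(deployments.items()):
        d = start
        while d <= end:
            rows.append(
                {"animal_id": animal_id, "date": d,
                 "n_interactions": counts.get((animal_id, d), 0)}
            )
            d += timedelta(days=1)
    return pd.DataFrame(rows, columns=["animal_id", "date", "n_interactions"])


def mean_daily_rate(totals, days) -> float:
    """Mean over animals of (total interactions / deployment days)."""
    totals = np.asarray(totals, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("deployment days must be positive")
    return float(np.mean(totals / days))


def monthly_summary(
    events: list[InteractionEvent],
    n_animals: int,
    exclude_months: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Per-month totals, per-animal means and min–max ranges.

    The mean divides by the full number of collared animals; animals with
    no event in a month contribute 0 to the range.
    """
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    df = events_to_frame(events)
    months = sorted({e.month for e in events} - set(exclude_months))
    animals = sorted({e.animal_id for e in events})
    rows = []
    for m in months:
        sub = df[df["month"] == m]
        per_animal = [int((sub["animal_id"] == a).sum()) for a in animals]
        per_animal += [0] * (n_animals - len(animals))
        total = int(len(sub))
        rows.append(
            {
                "month": m,
                "total": total,
                "mean": total / n_animals,
                "range_min": min(per_animal) if per_animal else 0,
                "range_max": max(per_animal) if per_animal else 0,
            }
        )
    return pd.DataFrame(rows, columns=["month", "total", "mean", "range_min", "range_max"])


def breakdown_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Counts → percentages (of the grand total), one row per key."""
    total = sum(counts.values())
    rows = [
        {"key": k, "count": int(v), "pct": (100.0 * v / total) if total else 0.0}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows, columns=["key", "count", "pct"])


def category_breakdown(events: list[InteractionEvent]) -> dict[str, pd.DataFrame]:
    """Event shares by surface category, and by labelled surface within each.

    Returns ``{"by_category": ..., "by_label": {category: ...}}`` where the
    per-label percentages are relative to that category's total.
    """
    by_cat: dict[str, int] = {c: 0 for c in ("runway", "taxiway", "connecting")}
    by_label: dict[str, dict[str, int]] = {c: {} for c in by_cat}
    for e in events:
        c = e.category
        by_cat[c] += 1
        key = e.label or e.surface_id
        by_label[c][key] = by_label[c].get(key, 0) + 1
    return {
        "by_category": breakdown_from_counts(by_cat),
        "by_label": {c: breakdown_from_counts(d) for c, d in by_label.items()},
    }


@dataclass(frozen=True)
class PopulationExtrapolation:
    interactions_per_day: float
    occupancy_s_per_day: float | None = None

    @property
    def occupancy_h_per_day(self) -> float | None:
        return None if self.occupancy_s_per_day is None else self.occupancy_s_per_day / 3600.0


def population_extrapolation(
    mean_rate_per_animal_day: float,
    population_size: float,
    mean_event_duration_s: float | None = None,
) -> PopulationExtrapolation:
    """Scale the per-animal daily interaction rate to the whole population.

    Occupancy assumes non-concurrent events: total daily seconds any animal
    spends on tarmac = events/day × mean event duration.
    """
    if mean_rate_per_animal_day < 0 or population_size < 0:
        raise ValueError("inputs must be nonnegative")
    per_day = mean_rate_per_animal_day * population_size
    occ = None
    if mean_event_duration_s is not None:
        if mean_event_duration_s < 0:
            raise ValueError("duration must be nonnegative")
        occ = per_day * mean_event_duration_s
    return PopulationExtrapolation(interactions_per_day=per_day, occupancy_s_per_day=occ)


def trimmed_mean_excluding(n: int, mean: float, excluded) -> float:
    """Mean after dropping known outlier values from a (n, mean) summary.

    Useful when only a sample size, its mean and the individual outliers
    are reported: (n·mean − Σ outliers) / (n − k).
    """
    excluded = list(excluded)
    k = len(excluded)
    if k >= n:
        raise ValueError("cannot exclude every observation")
    return (n * mean - sum(excluded)) / (n - k)
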