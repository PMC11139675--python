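"""Step-length, daily-distance and cumulative monthly movement summaries.

Distances are planar Euclidean sums over the straight steps between
consecutive fixes, so they under-measure any tortuosity between fixes and
are conservative. A step is assigned wholly to the local calendar date of
its earlier fix; steps spanning midnight are not split.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date as date_t, timedelta

import numpy as np
import pandas as pd

from .rank_stats import PairwiseResult, RankTestResult, dunn_posthoc, kruskal_wallis
from .trajectory_io import Step


def daily_distance(
    steps: list[Step],
    deployments: dict[str, tuple[date_t, date_t]] | None = None,
) -> pd.DataFrame:
    """Per-animal per-local-day travelled distance in km.

    If ``deployments`` is given, every date in each animal's window appears
    (zero-filled); otherwise only dates with at least one step appear.
    """
    acc: dict[tuple[str, date_t], float] = {}
    for s in steps:
        key = (s.animal_id, s.t_event.date())
        acc[key] = acc.get(key, 0.0) + s.length_m
    rows = []
    if deployments is not None:
        for animal_id, (start, end) in sorted(deployments.items()):
            d = start
            while d <= end:
                rows.append(
                    {"animal_id": animal_id, "date": d,
                     "distance_km": acc.get((animal_id, d), 0.0) / 1000.0}
                )
                d += timedelta(days=1)
    else:
        for (animal_id, d), m in sorted(acc.items()):
            rows.append({"animal_id": animal_id, "date": d, "distance_km": m / 1000.0})
    return pd.DataFrame(rows, columns=["animal_id", "date", "distance_km"])


def _month_fully_covered(year: int, month: int, start: date_t, end: date_t) -> bool:
    first = date_t(year, month, 1)
    last = date_t(year, month, calendar.monthrange(year, month)[1])
    return start <= first and last <= end


def monthly_cumulative(
    daily: pd.DataFrame,
    deployments: dict[str, tuple[date_t, date_t]] | None = None,
    full_months_only: bool = True,
    keep_months: tuple[tuple[int, int], ...] = (),
) -> pd.DataFrame:
    """Cumulative distance per animal per calendar month, plus the collective sum.

    With ``full_months_only`` a month is kept for an animal only if its
    collar recorded over the entire calendar month; ``keep_months`` lists
    (year, month) exceptions retained regardless (e.g. a first partial month
    shared by every collar). Returns rows per (animal, month) and per-month
    ``__collective__`` rows summing over animals.
    """
    df = daily.copy()
    df["month"] = pd.PeriodIndex([pd.Period(d, freq="M") for d in df["date"]])
    agg = (
        df.groupby(["animal_id", "month"], observed=True)["distance_km"]
        .sum()
        .reset_index()
    )
    if full_months_only:
        if deployments is None:
            raise ValueError("full_months_only requires deployment windows")
        keep = set(keep_months)
        mask = []
        for _, row in agg.iterrows():
            per = row["month"]
            if (per.year, per.month) in keep:
                mask.append(True)
                continue
            start, end = deployments[row["animal_id"]]
            mask.append(_month_fully_covered(per.year, per.month, start, end))
        agg = agg[np.asarray(mask, dtype=bool)]
    coll = (
        agg.groupby("month", observed=True)["distance_km"]
        .sum()
        .reset_index()
        .assign(animal_id="__collective__")
    )
    return pd.concat([agg, coll], ignore_index=True)[
        ["animal_id", "month", "distance_km"]
    ]


@dataclass
class MonthlyDistanceReport:
    kw: RankTestResult
    pairwise: list[PairwiseResult]
    months: list[int]
    excluded_months: list[int]

    def to_dict(self) -> dict:
        return {
            "kruskal_wallis": {
                "H": self.kw.H, "df": self.kw.df, "p": self.kw.p,
                "group_sizes": list(self.kw.group_sizes),
            },
            "months": self.months,
            "excluded_months": self.excluded_months,
            "pairwise": [
                {"a": r.group_a, "b": r.group_b, "z": r.z,
                 "p_raw": r.p_raw, "p_adjusted": r.p_adjusted}
                for r in self.pairwise
            ],
        }


def monthly_distance_test(
    daily: pd.DataFrame, exclude_months: tuple[int, ...] = ()
) -> MonthlyDistanceReport:
    """Kruskal–Wallis + Dunn/BH on daily distances grouped by calendar month."""
    df = daily[~daily["date"].map(lambda d: d.month).isin(exclude_months)]
    months = sorted({d.month for d in df["date"]})
    groups = [
        df[df["date"].map(lambda d: d.month) == m]["distance_km"].to_numpy()
        for m in months
    ]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two month groups after exclusion")
    kw = kruskal_wallis(groups)
    pw = dunn_posthoc(groups, labels=months)
    return MonthlyDistanceReport(
        kw=kw, pairwise=pw, months=months, excluded_months=sorted(exclude_months)
    )


def step_length_summary(
    steps: list[Step], max_duration_s: float | None = 1200.0
) -> pd.DataFrame:
    """Mean ± SD of step length (m), pooled and per animal.

    ``max_duration_s`` restricts to short-schedule steps (default 20 min),
    isolating the fine-scale active fix interval from long resting gaps;
    pass None to use all steps. A single-step group reports SD 0 and is
    flagged degenerate.
    """
    use = [
        s for s in steps
        if max_duration_s is None or s.duration_s <= max_duration_s
    ]
    rows = []

    def _row(animal_id: str, lengths: np.ndarray) -> dict:
        return {
            "animal_id": animal_id,
            "n": int(lengths.size),
            "mean_m": float(lengths.mean()) if lengths.size else float("nan"),
            "sd_m": float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
            "degenerate": lengths.size < 2,
        }

    animals = sorted({s.animal_id for s in use})
    for a in animals:
        lengths = np.array([s.length_m for s in use if s.animal_id == a])
        rows.append(_row(a, lengths))
    rows.append(_row("__pooled__", np.array([s.length_m for s in use])))
    return pd.DataFrame(rows, columns=["animal_id", "n", "mean_m", "sd_m", "degenerate"])
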