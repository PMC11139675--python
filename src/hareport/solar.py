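"""Sunrise/sunset computation and sun-anchored activity offsets.

Hares are crepuscular, so event times are more informative relative to the
sun than on the wall clock: each event is converted into a signed offset in
hours from its solar reference — sunrise for events between 00:00 and 11:59
local, sunset for events between 12:00 and 23:59 — positive in daylight,
negative in darkness. Sunrise/sunset are computed with the NOAA solar
position equations (zenith 90.833°, i.e. including standard refraction and
the solar disc radius), accurate to within ~2 minutes of published almanac
tables at mid-latitudes; a lookup table can override the computation.

Seasons follow the meteorological convention: winter = Dec–Feb,
spring = Mar–May, summer = Jun–Aug, autumn = Sep–Nov.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from datetime import date as date_t, datetime, time, timedelta, timezone
from pathlib import Path

import numpy as np

from .rank_stats import RankTestResult, PairwiseResult, dunn_posthoc, kruskal_wallis
from .trajectory_io import to_local_time

SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(d: date_t) -> str:
    """Meteorological season of a local calendar date."""
    return SEASONS[d.month]


@dataclass(frozen=True)
class SolarDay:
    date: date_t
    lat: float
    lon: float
    sunrise_local: datetime
    sunset_local: datetime

    @property
    def daylight_hours(self) -> float:
        return (self.sunset_local - self.sunrise_local).total_seconds() / 3600.0


@dataclass(frozen=True)
class OffsetValue:
    t_local: datetime
    reference_event: str  # "sunrise" | "sunset"
    offset_h: float  # signed hours; positive in daylight
    is_daylight: bool


# --- NOAA solar position -------------------------------------------------

_ZENITH_DEG = 90.833  # official sunrise/sunset zenith


def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (deg) at Julian century jc."""
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )
    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * e * math.sin(mr)
        + 4.0 * e * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr)
    )
    return eot, decl


def _julian_century(d: date_t, minutes_utc: float) -> float:
    # Julian day from Gregorian date
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    jd = math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d.day + b - 1524.5
    return (jd + minutes_utc / 1440.0 - 2451545.0) / 36525.0


def _hour_angle_deg(lat: float, decl: float) -> float:
    latr, dr = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(latr) * math.cos(dr))
        - math.tan(latr) * math.tan(dr)
    )
    if cos_ha > 1.0 or cos_ha < -1.0:
        raise ValueError(
            "polar day/night: no sunrise/sunset on this date; supply a lookup table"
        )
    return math.degrees(math.acos(cos_ha))


def sun_times(d: date_t, lat: float, lon: float, zone: str = "Europe/Dublin") -> SolarDay:
    """Sunrise and sunset (local civil time) for one date and site.

    ``lon`` is degrees East (negative West). Two refinement passes of the
    NOAA equations — evaluating the equation of time and declination at the
    provisional event time — bring accuracy to within ~1–2 minutes.
    """
    if abs(lat) >= 66.0:
        raise ValueError("latitude too close to polar circle; supply a lookup table")

    def _event(minute_guess: float, sign: float) -> float:
        minutes = minute_guess
        for _ in range(2):
            jc = _julian_century(d, minutes)
            eot, decl = _solar_params(jc)
            noon = 720.0 - 4.0 * lon - eot
            ha = _hour_angle_deg(lat, decl)
            minutes = noon + sign * 4.0 * ha
        return minutes

    rise_min = _event(720.0, -1.0)
    set_min = _event(720.0, +1.0)
    midnight_utc = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    sunrise = to_local_time(midnight_utc + timedelta(minutes=rise_min), zone)
    sunset = to_local_time(midnight_utc + timedelta(minutes=set_min), zone)
    return SolarDay(date=d, lat=lat, lon=lon, sunrise_local=sunrise, sunset_local=sunset)


class SunTimeSource:
    """Provides SolarDay per date: NOAA computation with optional CSV override.

    The lookup CSV has columns ``date, sunrise_local, sunset_local``
    (ISO date, HH:MM[:SS] local clock times).
    """

    def __init__(self, lat: float, lon: float, zone: str = "Europe/Dublin",
                 lookup_csv=None):
        self.lat, self.lon, self.zone = lat, lon, zone
        self._lookup: dict[date_t, tuple[time, time]] = {}
        self._cache: dict[date_t, SolarDay] = {}
        if lookup_csv is not None:
            with open(lookup_csv, newline="") as fh:
                for row in csv.DictReader(fh):
                    d = date_t.fromisoformat(row["date"].strip())
                    self._lookup[d] = (
                        time.fromisoformat(row["sunrise_local"].strip()),
                        time.fromisoformat(row["sunset_local"].strip()),
                    )

    def __call__(self, d: date_t) -> SolarDay:
        if d in self._cache:
            return self._cache[d]
        if d in self._lookup:
            rise_t, set_t = self._lookup[d]
            tz = to_local_time(datetime(d.year, d.month, d.day, 12, tzinfo=timezone.utc), self.zone).tzinfo
            day = SolarDay(
                date=d, lat=self.lat, lon=self.lon,
                sunrise_local=datetime.combine(d, rise_t, tzinfo=tz),
                sunset_local=datetime.combine(d, set_t, tzinfo=tz),
            )
        else:
            day = sun_times(d, self.lat, self.lon, self.zone)
        self._cache[d] = day
        return day


# --- signed offsets ------------------------------------------------------

def offset_event(t_local: datetime, solar: SolarDay) -> OffsetValue:
    """Signed sun-anchored offset of one event.

    Events on the morning clock half (00:00–11:59) are referenced to
    sunrise, afternoon/evening events (12:00–23:59) to sunset. The offset
    magnitude is the time from the reference in hours; the sign is positive
    iff the event falls between sunrise and sunset (daylight), with 0 at
    the boundary.
    """
    ref_name = "sunrise" if t_local.hour < 12 else "sunset"
    ref = solar.sunrise_local if ref_name == "sunrise" else solar.sunset_local
    magnitude = abs((t_local - ref).total_seconds()) / 3600.0
    is_daylight = solar.sunrise_local <= t_local <= solar.sunset_local
    sign = 1.0 if is_daylight else -1.0
    return OffsetValue(
        t_local=t_local,
        reference_event=ref_name,
        offset_h=sign * magnitude,
        is_daylight=is_daylight,
    )


def offsets_for_events(times_local, sun_source: SunTimeSource) -> list[OffsetValue]:
    """Offset every event time against its own date's sun times."""
    return [offset_event(t, sun_source(t.date())) for t in times_local]


# --- seasonal comparison -------------------------------------------------

@dataclass
class SeasonalOffsetReport:
    kw: RankTestResult | None
    pairwise: list[PairwiseResult]
    summaries: dict[str, dict[str, float]]  # season -> n/mean/median/q25/q75
    excluded: list[str]

    def to_dict(self) -> dict:
        out = {
            "summaries": self.summaries,
            "excluded_groups": self.excluded,
            "pairwise": [
                {"a": r.group_a, "b": r.group_b, "z": r.z,
                 "p_raw": r.p_raw, "p_adjusted": r.p_adjusted}
                for r in self.pairwise
            ],
        }
        if self.kw is not None:
            out["kruskal_wallis"] = {
                "H": self.kw.H, "df": self.kw.df, "p": self.kw.p,
                "group_sizes": list(self.kw.group_sizes),
            }
        return out


def seasonal_offset_comparison(offsets_by_season: dict[str, list[float]]) -> SeasonalOffsetReport:
    """Kruskal–Wallis + Dunn/BH on signed offsets grouped by season.

    Seasons with fewer than 2 observations are excluded (recorded in the
    report); at least two usable seasons are required.
    """
    usable = {s: np.asarray(v, dtype=float) for s, v in offsets_by_season.items() if len(v) >= 2}
    excluded = sorted(set(offsets_by_season) - set(usable))
    summaries = {
        s: {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
        for s, v in usable.items()
    }
    if len(usable) < 2:
        raise ValueError("need at least two seasons with >=2 observations")
    labels = sorted(usable)
    groups = [usable[s] for s in labels]
    kw = kruskal_wallis(groups)
    pw = dunn_posthoc(groups, labels=labels)
    return SeasonalOffsetReport(kw=kw, pairwise=pw, summaries=summaries, excluded=excluded)


# --- clock-time histogram ------------------------------------------------

def clock_histogram(times_local, bin_h: int = 3) -> np.ndarray:
    """Percentage of events per local-time-of-day bin.

    Bins are anchored at local midnight, ``bin_h`` hours wide and
    right-open (bin 05:00–07:59 holds events with 5 ≤ hour < 8). Returns an
    array of 24/bin_h shares summing to 100 (all-zero for no events).
    """
    if 24 % bin_h != 0:
        raise ValueError("bin_h must divide 24")
    n_bins = 24 // bin_h
    counts = np.zeros(n_bins)
    times_local = list(times_local)
    for t in times_local:
        h = t.hour + t.minute / 60.0 + t.second / 3600.0
        counts[int(h // bin_h)] += 1
    total = counts.sum()
    return counts / total * 100.0 if total > 0 else counts


def clock_bin_labels(bin_h: int = 3) -> list[str]:
    return [
        f"{b * bin_h:02d}:00–{(b + 1) * bin_h - 1:02d}:59"
        for b in range(24 // bin_h)
    ]
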