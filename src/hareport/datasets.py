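"""Published summary statistics from the Dublin Airport hare-collar study.

The raw relocations from the December 2021 – August 2022 Irish hare
(*Lepus timidus hibernicus*) deployment are access-restricted, but the
study's per-collar and per-month summary tables are public. They are kept
here as inputs so that derived quantities — daily interaction rates,
category percentages, population extrapolations, home-range means — can be
recomputed and cross-checked with package functions.
"""

from __future__ import annotations

import pandas as pd

STUDY_SITE = {"lat": 53.4264, "lon": -6.2499, "tz": "Europe/Dublin"}

#: per-collar deployment summary (one row per hare)
COLLAR_SUMMARY = pd.DataFrame(
    [
        # id,  sex, area,     days, fixes, interactions, pct_fixes_interacting
        ("8581", "M", "Area 1", 226, 17_764, 2239, 12.6),
        ("8582", "M", "Area 1", 195, 18_829, 1798, 9.5),
        ("8583", "M", "Area 2", 213, 19_513, 164, 0.8),
        ("8584", "M", "Area 2", 217, 19_926, 341, 1.7),
        ("8585", "F", "Area 2", 260, 15_650, 29, 0.2),
    ],
    columns=["animal_id", "sex", "area", "days", "n_fixes", "n_interactions",
             "pct_fixes_interacting"],
)

N_ANIMALS = len(COLLAR_SUMMARY)

#: monthly interaction totals (July excluded: single collar still running)
MONTHLY_INTERACTIONS = pd.DataFrame(
    [
        ("December", 583, 116.6, 2, 421),
        ("January", 595, 119.0, 7, 330),
        ("February", 654, 130.8, 0, 467),
        ("March", 702, 140.4, 0, 379),
        ("April", 1073, 214.6, 14, 531),
        ("May", 502, 100.4, 0, 295),
        ("June", 391, 78.2, 0, 339),
    ],
    columns=["month", "total", "mean", "range_min", "range_max"],
)

#: interaction counts by surface category and by labelled surface
CATEGORY_COUNTS = {"runway": 1706, "taxiway": 2502, "connecting": 363}
RUNWAY_COUNTS = {"16-34": 1564, "10L-28R": 116, "10R-28L": 26}
AREA1_ANIMALS = ("8581", "8582")

#: estimated airfield hare population (collar rates scale to this)
POPULATION_SIZE = 118

#: direct observations of tarmac dwell time: 31 sightings, mean 67 s, of
#: which two were long rests on an inactive runway (971 s and 553 s)
DWELL_N = 31
DWELL_MEAN_S = 67.0
DWELL_OUTLIERS_S = (971.0, 553.0)

#: 95% KUD home-range areas per collar, hectares
HOME_RANGE_AREAS_HA = [36.0, 33.6, 27.6, 28.7, 12.2]
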