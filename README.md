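# hareport

Movement-ecology analysis of GPS-collared mammals living airside at an
airport — built around the Irish hare (*Lepus timidus hibernicus*)
population at Dublin Airport, where hares cross the runway and taxiway
system and therefore pose a wildlife-strike risk.

The package is a reusable pipeline for the complete analysis:

* **Ingest & QC** — Movebank-style GPS fix tables; horizontal-accuracy
  cutoff (> 30 m removed, matching runway/taxiway widths of ~60 / ~35 m),
  5-day post-capture burn-in, UTC → DST-aware local time, projection to a
  planar metric frame.
* **Interaction counting** — a *tarmacked-area interaction* is an
  intersection between the straight step joining two consecutive fixes and
  a runway / taxiway / connecting-strip polygon; each intersected surface
  per step is one independent event. Daily, monthly and per-category
  summaries, plus population-level extrapolation (rate × population, and
  occupancy seconds under non-concurrent events).
* **Sun-anchored activity** — NOAA sunrise/sunset; each event becomes a
  signed offset in hours (sunrise reference for 00:00–11:59 events, sunset
  for 12:00–23:59; positive in daylight), compared across seasons with
  Kruskal–Wallis + Dunn post hoc under Benjamini–Hochberg correction.
* **Movement metrics** — step lengths, daily distances, cumulative monthly
  distances restricted to fully-covered calendar months.
* **Home ranges** — kernel utilisation distributions with the reference
  bandwidth `h_ref = sigma_hat * n^(-1/6)`,
  `sigma_hat = sqrt((var_x + var_y)/2)`; 95% contours as the smallest
  region holding 0.95 probability; areas and habitat composition
  (tarmac / apron / built land / grassland / service roads / unknown /
  outside the mapped airfield).
* **Synthetic data** — a parametric airfield (60 m runways, 35 m taxiways,
  connecting strips, grassland islands) and a two-state movement simulator
  (crepuscular activity anchored to sunrise/sunset, correlated random walk
  with homing, state-dependent 10-min/6-h fix schedule, accuracy-scaled
  GPS noise) with a full ground-truth log, so every stage is testable
  without restricted field data.

## Worked example

```python
from hareport import scenario_study_like
from hareport.pipeline import RunConfig, run_pipeline
from hareport.synthetic import write_scenario

bundle = scenario_study_like(seed=42, n_days=30)   # 5 animals, Dec 5 start
paths = write_scenario(bundle, "simdir")
cfg = RunConfig(gps_csv=paths["fixes"], map_geojson=paths["airfield"],
                out_dir="outdir", site_lat=53.4264, site_lon=-6.2499)
result = run_pipeline(cfg)
print(result.table1[["animal_id", "n_fixes", "n_interactions",
                     "pct_fixes_interacting"]].to_string(index=False))
```

prints

```
animal_id  n_fixes  n_interactions  pct_fixes_interacting
      H01      545             102                   18.7
      H02      628              96                   15.3
      H03      709               2                    0.3
      H04      676               2                    0.3
      H05      632               5                    0.8
```

H01 and H02 live beside the semi-operational northern runway and interact
with tarmac in 15–19% of their movement steps; the three animals in
distant grassland almost never do — the qualitative contrast observed in
the field study. The per-animal `pct_fixes_interacting` column is
`interactions / fixes × 100`; `result.table2` gives monthly totals and
per-animal means; `result.table3` gives 95% KUD areas (here ~28–34 ha)
with habitat shares summing to 1.

The `examples/` directory holds one short narrative script per
capability: simulation + QC, interaction counting + solar offsets, home
ranges, and the full pipeline.

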