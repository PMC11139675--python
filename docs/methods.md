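# Methods

## Coordinate frame and quality control

All geometry is planar. Longitude/latitude are projected with a spherical
transverse-Mercator frame centred on the study site (or the data bounding
box when no site is given). Over an airfield a few kilometres across the
difference from an ellipsoidal projection is millimetres — far below GPS
error — so distances and areas are treated as exactly Euclidean.

Quality control applies two filters, in this order per fix:

* horizontal accuracy **strictly greater than 30 m** → removed. The cutoff
  sits below the narrowest tarmac surface (taxiways ~35 m), so a retained
  fix cannot be displaced across a surface by its stated error alone.
  Fixes with a *missing* accuracy value are retained and logged — the
  filter applies only to values actually reported.
* fixes earlier than `deploy_start + 5 × 24 h` → removed (post-capture
  burn-in, measured from the first timestamp, whole days). This avoids
  handling-influenced movement.

Filtering is idempotent, and all removals are counted by reason. Steps are
built between consecutive retained fixes; a trajectory of n fixes yields
exactly n−1 steps. Zero-length steps are kept (they carry time) but
flagged degenerate and excluded from geometric intersection tests. Steps
spanning long resting gaps are ordinary steps; an optional flag annotates
durations above a threshold without dropping anything, because every pair
of consecutive fixes is evidence of net displacement.

## Interaction counting

The counting unit is the **(step, polygon) pair**: one event per tarmacked
polygon whose geometry intersects the step's segment. A step that crosses
a runway and then its parallel taxiway yields two events (two independent
strike opportunities); a step that enters, exits and re-enters the same
polygon yields one. Boundary grazing counts — "intersects" is used without
qualification, which keeps the rule deterministic. Events are ordered by
(animal, time, surface id) for reproducible output. A step's timestamp is
the **earlier fix** (the event had begun by then; the later fix would
anchor some events on the wrong calendar day).

Limitations: a crossing that begins and ends between two fixes (an
out-and-back faster than the 10-min schedule) is invisible to any
fix-based method; counts are therefore conservative. Apron and service
roads are not interaction surfaces — only runways, taxiways and connecting
strips carry strike risk, regardless of their activity status (inactive
tarmac is still tarmac).

Aggregations: zero-filled per-animal daily counts over each deployment
window; monthly totals with mean = total / number of collared animals and
per-animal min–max ranges (months excludable, e.g. a month covered by only
one collar); category and per-surface percentage breakdowns; population
extrapolation `events/day = per-animal rate × population size` and
occupancy `seconds/day = events/day × mean event duration`, which assumes
non-concurrent events and so is an upper bound on simultaneous presence.

## Sun-anchored offsets

Sunrise/sunset come from the NOAA solar-position equations (zenith
90.833°), with two refinement passes evaluating the equation of time and
declination at the provisional event time; agreement with published tables
at the study latitude is within ~2 minutes, and an injected lookup CSV
overrides computation when exact published times are preferred. A single
reference lat/lon serves the whole site (the airfield spans far less than
one solar minute). Polar latitudes are rejected with a pointer to the
lookup table.

Each event's offset: reference = sunrise if the local clock time is before
12:00, else sunset; magnitude = |event − reference| in hours; sign
positive iff the event lies between sunrise and sunset. Offsets are kept
as continuous hours — the field convention quotes values like "+3 h
30 min", so no integer rounding is applied. The 12:00 split uses DST-aware
civil time. Clock histograms use bins anchored at local midnight,
right-open, default 3 h.

Seasons are meteorological (winter = Dec–Feb, spring = Mar–May,
summer = Jun–Aug, autumn = Sep–Nov) from the local date. Seasonal offset
comparison: Kruskal–Wallis across seasons, Dunn pairwise z with BH
adjustment, per-season summaries; seasons with fewer than two observations
are excluded with a warning, and the whole test is skipped (reported, not
raised) when fewer than two usable seasons remain — a sub-season study
window is a legitimate input.

## Rank statistics

Kruskal–Wallis uses mid-ranks for ties and the chi-square approximation
with k−1 df; group sizes in this pipeline are large enough that exact
small-sample tables add nothing. The tie-corrected statistic is
H/C with C = 1 − Σ(t³−t)/(N³−N); all-tied data yield H = 0 with a warning
rather than 0/0. Dunn's z uses the pooled mean-rank variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p-values, BH-adjusted
across all pairs. BH is the standard step-up with monotonicity enforcement
and capping at 1, original order preserved. Calibration: over 2,000 null
simulations (k = 3, n = 15/group) the empirical type-I error at α = 0.05
lands at ~0.04–0.05 — the chi-square approximation is mildly conservative
at this group size, inside the accepted 0.05 ± 0.02 band.

## Movement metrics

A step belongs wholly to the local date of its earlier fix; midnight
spanners are not split (simplest deterministic rule; the daily totals sum
exactly to total path length either way). Daily distances are planar
Euclidean sums in km and zero-filled over deployment windows. Monthly
cumulative distances keep a month for an animal only if the collar covered
the entire calendar month, with explicit (year, month) exceptions for a
first partial month shared by every collar. Step-length summaries restrict
by default to steps ≤ 20 min, isolating the 10-min active schedule from
6-h resting gaps.

## Kernel home ranges

The utilisation distribution is an isotropic bivariate Gaussian KDE with
the reference bandwidth `h_ref = sigma_hat · n^(−1/6)`,
`sigma_hat = sqrt((var_x + var_y)/2)` (sample variances). The grid covers
the point bounding box expanded by 3h per side, 200 cells per axis,
refined until the cell is at most h/2; the density is renormalised on the
grid so Σ density × cell area = 1. All fixes enter equally — weighting the
6-h resting fixes differently would need a behavioural model the data do
not support.

The 95% home range accumulates cells from densest downward until 0.95
probability is captured; the last admitted cell's density is the contour
threshold, polygonised by marching squares (zero-padded so edge-touching
contours close; containment parity assembles shells and holes). Areas come
from the polygons, not cell counts. Habitat composition intersects the
home-range polygons with each habitat class union; area covered by no
mapped surface — including beyond the airfield boundary — is reported as
`outside`, and shares sum to 1.

Known bias: the kernel inflates each axis variance by ~h², so estimated
95% areas overestimate the underlying region by roughly (1 + h²/σ²) and
converge from above as n grows (h_ref → 0). The calibration suite measures
exactly this: mean areas over replicated draws from an isotropic normal at
n = 200/1,000/5,000 shrink monotonically toward the analytic area
π σ² χ²₂(0.95), ending within a few percent. Replication matters — a
single draw's area has ~8% noise at n = 200, so the convergence check
averages 80/40/10 replicates per n.

## Synthetic data: what it emulates, and what it does not

The airfield is parametric and deterministic: two 3,000 × 60 m runways
with parallel 35 m taxiways and abutting 20 m connecting strips (no
tarmac overlap — shared edges only), grassland islands, marginal apron /
built-land / service-road / unknown surfaces, and a perimeter boundary.
The northern runway is semi-operational with an inactive taxiway, the
southern pair active — mirroring a field with mixed activity statuses.

Movement is a two-state process on a 1-min step. The activity probability
is a baseline (0.10) plus Gaussian bumps (amplitude 0.75, width 1.5 h)
centred on sunrise and sunset — the simplest crepuscular model. States
switch by redrawing at a hazard of 1/mean-bout (active 60 min, rest
180 min), giving geometric dwell times that track the target probability.
Active motion is a correlated random walk: gamma speeds (mean 8 m/min,
shape 4), von Mises turning (κ = 4), and a linear pull of 1.2%/min toward
the home centre, giving stationary spreads of ~90–120 m and 10-min step
lengths of a few tens of metres, comparable to collared hares. Resting is
stationary. The fix schedule fires once the time since the last fix
reaches the current state's interval (10 min active, 6 h resting), so the
fine schedule resumes promptly when activity restarts — emulating
accelerometer-informed collars. GPS noise is Gaussian with sd = 0.5 × the
drawn accuracy value; 2% of accuracy draws exceed the 30 m cutoff, so the
QC stage has real work to do.

The default scenario places two animals ~100–170 m from the northern
tarmac and three in grassland ~300 m from the southern runway. Those
distances were chosen so the scenario reproduces the field study's
qualitative design: every animal interacts occasionally, near-tarmac
animals at ≥10× the rate of distant ones, and no animal has interactions
on more than 20% of its steps.

Ground truth logs the dense path, the state sequence, every connected
interval of the true path inside each tarmac polygon (per interval, per
polygon — note this differs from the per-(step, polygon) detection unit:
one detected event can cover several short true intervals, and a true
interval without any fix inside it can be missed entirely), and the true
daily path length, which bounds the fix-based estimate from above since
straight steps under-measure tortuosity.

Not emulated: the raw accelerometer signal (the active/resting state
drives the schedule directly), demographic processes, aircraft traffic,
perimeter fences, and habitat preference beyond home-centre placement.
Passing tests therefore demonstrate the pipeline's correctness on
known-truth data with realistic sampling structure — not that real hares
move like the simulator.

## Problem sizes and determinism

The test suite and acceptance script run the scenario at 5 animals ×
30 days (≈ 4,000 fixes), the oracle-equivalence check at 1,000 random
segment/map cases against a 1 cm point-sampling oracle, the home-range
calibration at n ∈ {200, 1,000, 5,000} with replication as above, and the
rank-test calibration at 2,000 null simulations. Every stochastic
component draws from `numpy.random.default_rng` seeded explicitly;
identical seeds give byte-identical CSV/GeoJSON outputs and reports.
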