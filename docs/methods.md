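# Methods

This note documents the models implemented in `medaccess`, the defaults and
why they were chosen, what the synthetic-city generator does and does not
emulate, and the numerical conventions that affect results.

## The synthetic city

The generator produces a planar city in an abstract projected CRS (meters,
origin at the south-west corner).  No geodesy is involved: the analyses the
package implements operate on projected coordinates, and an abstract plane
keeps every stage exactly testable.

**Residential areas** are points (compound centroids) with integer household
counts.  They are drawn from a two-component mixture: a Gaussian "old core"
cluster (default 60% of areas, σ = extent/10 around a core center at
(0.40 W, 0.55 H)) and a uniform "new periphery".  This reproduces the
dense-core / sparse-periphery gradient that drives the mismatch analyses.
Household counts are uniform on a configurable range (default 50–800);
persons = households × 2.5 by default.  The persons-per-household constant
is explicit and configurable because demand capacities are
person-denominated while compounds carry household counts.

**Facilities** come in three tiers with defaults matching the tiered
planning standards the analysis assumes:

| tier | service radius | capacity (persons) | default count |
|---|---|---|---|
| city | 5,000 m | 260,000 | 5 |
| district | 3,000 m | 67,000 | 16 |
| community | 1,000 m | 15,000 | 56 |

Facilities are placed with a core bias (80% Gaussian around the core,
σ = extent/7, else uniform), so community-tier coverage stays well below
100% and the periphery is underserved — the regime the optimization stages
are designed for.  Default counts were chosen so a 12 × 12 km, 400-compound
city lands in that regime (community coverage roughly 50–60%, city tier
roughly 70–80%) while keeping every network computation fast.

**The road network** is a perturbed lattice (default 1 km spacing, 20%
jitter on interior nodes): the boundary ring is expressway (80 km/h), the
two central axes are primary (60 km/h), every fifth line is secondary
(40 km/h), the rest local (30 km/h).  Edge travel time is
length / speed.  The graph is connected by construction.

**Planted blind zones** are disks of residential areas guaranteed to be
outside every same-tier facility's network service radius.  Enforcement is
by exclusion: facilities may not be placed within
`zone radius + tier radius + 1,500 m` (euclidean) of a zone center, which
bounds the network distance from below because network distance can never
be shorter than the straight line minus the two access offsets.  After
generation the guarantee is *verified* with exact shortest paths; a violated
plant raises an error rather than being silently adjusted.  Placement uses
rejection sampling with a hard iteration cap, so an infeasible specification
(e.g. a zone so large that no facility fits outside its buffer) fails
loudly.

**Determinism.** One root seed; each stage (roads, residential, facilities,
beds) uses a child generator derived by a fixed offset, so stages are
individually reproducible and adding a stage never perturbs earlier ones.

What the generator does **not** emulate: real street topology (no one-way
streets, no grade separation), building footprints, vacancy (all households
count as occupied), temporal variation in travel speeds, and any
socio-economic heterogeneity in demand.  Passing tests therefore demonstrate
correctness of the algorithms under the assumed spatial structure, not
calibration to any real city.

## Network distances

Off-network points are snapped to their nearest road segment; the segment is
split at the projection point so distances are measured along the network
from the true access location.  Every distance includes the perpendicular
access offsets of both endpoints (`d = off_i + path + off_j`), preventing
free coverage of off-network points.  Points farther than the snap tolerance
(default 500 m) from every edge are flagged unreachable and count as
uncovered — the conservative choice.  Co-located origin–destination pairs
have distance zero by definition.  Travel time uses the same paths under the
`time_min` edge weight; access offsets are traversed at the snapped edge's
speed.

Service-area queries run radius-truncated single-source Dijkstra per
facility (cutoff adjusted for the facility's own access offset); the test
suite checks exact agreement with untruncated all-pairs Dijkstra computed by
an independent implementation.

## Diagnostics

**KDE.** `D(x,y) = h⁻² Σ wᵢ K(dᵢ/h)` evaluated at grid cell centers.  The
default kernel is the finite-support quartic `K(u) = (3/π)(1−u²)²` for
u < 1 (unit integral on the disk), the common GIS choice; a Gaussian is
available.  The bandwidth default is extent-diagonal / 30 — a pragmatic
smoothing level for city-scale rasters — always user-settable and recorded
in the output metadata, since no principled value exists for arbitrary point
patterns.

**Standard deviational ellipse.**  Weighted mean center; the major-axis
direction comes from the closed-form principal-axis solution
`φ = ½·atan2(2Sxy, Sxx − Syy)`; σ along the major and minor axes are the
square roots of the corresponding principal variances.  The azimuth is
reported in degrees clockwise from north in [0, 180), the GIS convention.
σ_major ≥ σ_minor always; collinear inputs degenerate to σ_minor = 0 with a
warning flag.

**Bivariate Moran's I.**  Implemented in the standard (GeoDa-style) form:
both variables z-standardized, weights row-standardized,
`I = z_x · (W z_y) / n`.  With y = x this reduces exactly to univariate
Moran's I, which the tests assert to 1e-12.  Default weights are queen
contiguity on the admin polygons, row-standardized.  Inference is a
conditional permutation test (default 999 permutations, seeded) with the
two-sided pseudo-p `(k+1)/(n_perm+1)`; local cluster classes (HH/LL/HL/LH)
are assigned only where the local pseudo-p ≤ α, from the sign quadrant of
(z_x, lag z_y).  Disconnected weights warn and proceed with zero lag for
isolated units; zero-variance inputs are rejected.

## Equity

Units are ordered by per-capita resource ascending — required for a proper
Lorenz curve.  Zero-population units with zero resource carry no information
and are dropped with a logged warning; zero-population units *with* resource
have undefined per-capita share and are rejected.  The Gini is the
trapezoidal complement `G = 1 − Σ (Pᵢ−Pᵢ₋₁)(Rᵢ+Rᵢ₋₁)`, which the tests
verify against the population-weighted mean-absolute-difference definition
to 1e-12.  The classification cutpoints 0.40 and 0.50 extend the common
convention that treats G = 0.4 as the inequality alert threshold; they are
reporting conventions for planning tables, not statistical results.

## Coverage and blind zones

Coverage is defined on **network distance in meters**, matching the
meter-valued tier radii; travel time is computed for reporting only (mean
minutes per plan).  Percentages are rounded half-up to two decimals, the
convention of printed planning tables (Python's banker's rounding would
disagree on ties).  Blind-zone clusters are connected raster regions of the
household-weighted KDE over uncovered points above the 0.90 quantile of
positive raster values — a documented free parameter, since no published
rule exists for delimiting deficiency areas; clusters are ranked by summed
uncovered households.

## Location-allocation

The model is **capacity-aware maximal coverage**: choose sites to maximise
the person-demand assignable within the service radius without exceeding any
site's capacity.  (A pure min-cost objective would contradict the coverage
statistics this model family reports; maximal coverage is the form that
reproduces them.)

**Assignment** processes all in-radius (site, demand) pairs in ascending
distance order; a demand takes the first site with enough residual capacity,
spilling to its next-nearest in-radius site when the nearest is full.
Demands are atomic (no splitting).  Ties break deterministically by site
order then demand order, with sites ordered fixed-first then candidates,
ascending id within each block.  Unassigned is a valid outcome.  Every
assignment asserts load ≤ capacity.

**Greedy selection** adds the candidate with the largest marginal
newly-assigned person-demand, re-running the full assignment per trial so
capacity spill is respected, and stops at a coverage target, a site budget,
or zero marginal gain.  Uncapacitated, this is the classical maximal-
coverage greedy with the (1−1/e) guarantee; the tests verify the bound
against an enumeration oracle and exact agreement with the optimum on the
shipped toy instances.  An unreachable coverage target returns the best plan
with an infeasibility flag.

**Increment mode** fixes all existing tier facilities and uses the currently
uncovered residential locations as candidates — new stations go where unmet
demand lives.  **Redistribution mode** fixes nothing: the candidate pool is
the union of existing locations and uncovered residential locations, and up
to `budget` sites (default: the existing count) are selected.  Relocation
accounting is explicit because published comparisons report relocation
counts without defining them: retained = selected ∩ existing,
relocations = min(|existing| − retained, |selected| − retained),
net change = |selected| − |existing|.

Plan coverage percentages count residential areas (the unit of published
coverage statistics) under the capacity-aware assignment; the person-demand
objective and the area-count statistic therefore coexist in every plan.

## Pipeline

`run_pipeline` executes all stages with a stage-scoped, machine-parsable log
and writes every intermediate artifact (GeoJSON, CSV, ESRI ASCII, JSON
plans, a Markdown summary) plus the resolved YAML config for provenance.
The validation summary reports per-tier coverage before/after optimization,
the improvement as an exact difference in percentage points, and the
**combined** coverage — the union of all tiers' optimized service areas —
which is implemented as a set union because no other aggregation is
well-defined on overlapping tiers.  Default problem sizes (400 residential
areas, 5/16/56 facilities, 6 new sites per hospital tier) keep a full run
under a minute on one CPU while preserving the core–periphery regime; all
sizes are configurable.

## Known limitations

* The exact MCLP oracle enumerates candidate subsets and is limited to 20
  candidates; no integer-programming backend is used.
* Greedy selection re-evaluates every candidate each round (no lazy
  evaluation); fine at the shipped problem sizes, quadratic in candidates.
* Capacitated coverage is not submodular, so the (1−1/e) bound applies only
  to the uncapacitated case; capacitated greedy is validated empirically
  against enumeration on small instances.
* Conditional permutation of local Moran statistics on very small or binary
  maps has limited attainable significance; global inference is the reliable
  signal there.
* Snapping assigns each point to its single nearest edge; a point equidistant
  from two edges resolves by edge order, which is deterministic but
  arbitrary.
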