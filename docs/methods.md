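# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic scenario generator does and
does not emulate. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Grid model and spatial conventions

All layers share one `GridSpec`: a north-up grid of square cells in a
planar (projected, meter) CRS, 0-based row-major indices, origin at the
top-left corner. Cell centers sit at `origin + (index + 0.5)·cell_size` and
point-to-cell mapping uses half-open intervals, so a point on a shared edge
belongs to the cell with the larger index. The default cell size is 1000 m
(1 km² = 100 ha per cell), the working resolution at which heterogeneous
administrative and ecological layers are unified. No geodesic computation
is performed anywhere; inputs are assumed already projected. Reprojection
between CRSs is out of scope.

GeoTIFF I/O is implemented on `tifffile` with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GDAL nodata). Only single-band north-up
files are accepted; rotated geotransforms and multi-band files raise a
format error. Nodata sentinels default to −9999.0 for continuous rasters
and 255 for label rasters, and nodata cells are excluded from every
statistic. In the weighted overlay, nodata in any input layer makes the
output cell nodata (missing information does not silently become zero).

Resampling supports `nearest` (sampling at target cell centers; the only
method permitted for categorical rasters), and `mean`/`sum` aggregation of
source cells by containing target cell; `sum` conserves the global total of
valid cells (checked to 1e-9 relative in the tests).

## Severity coefficient

Two record types are fused:

- **Presence–absence by district.** A cell in an infested district receives
  the host-preference weight of its land-use class, in [0, 1]. The default
  host table reflects a polyphagous defoliator that prefers broadleaf
  forest (1.0) and cropland (0.8), with low weights for other forest (0.4)
  and grassland (0.2) and zero for water/urban/bare. Weights are
  configurable per run.
- **Presence-only points.** Raw influence at a cell center is
  Σ_p 1/d(c,p)^power with power = 2 by default — the inverse-square
  distance-decay scheme, implemented as the power law it is written as. A
  cell containing a point is assigned the maximum finite influence found
  elsewhere on the grid before normalization (the d→0 cap, preserving
  "maximum at the source" without dividing by zero). The surface is then
  min–max normalized to [0, 1], which makes it invariant to duplicating
  points in place.

Severity = clip(w_pa·PA + w_po·PO, 0, 1). The source weights default to
(0.5, 0.5) — equal trust in the two record streams, since no principled
ratio is available — and are exposed in configuration. Normalization and
severity are computed per year from that year's records only; no temporal
decay or carry-over is applied. "Severe" cells are counted with a strict
inequality (severity > threshold, default 0.75) and reported with their
area in hectares.

## Dasymetric disaggregation

Allocation weights are provincial output intensities: sector output divided
by the area of the sector's linked land-use class(es) — cultivation→arable,
forestry→both forest classes, husbandry→grassland, fishery→water. Linkage
is strict (no cross-sector leakage into unlinked classes), and urban/bare
weights are forced to exactly zero. Within a district, a cell's share is
its class weight divided by the district's total weight mass, so cell sums
reproduce the district total by construction; districts with zero
allocation mass for a sector keep nodata cells and are flagged rather than
being spread uniformly. Weights are time-invariant. Currency is stored in
ten-thousand CNY. The reconstruction validator reports per-district
absolute percentage errors (infinite when a zero district total meets
nonzero cells) with max and mean summaries.

## GeoDetector

The factor detector uses population (divide-by-n) variances throughout:
with sample variances q can leave [0, 1] when strata are tiny, while the
population form keeps 0 ≤ q ≤ 1 exactly (law of total variance). Singleton
strata contribute zero within-stratum variance and are kept; a
minimum-stratum-size filter exists but is off by default. Two endpoints are
evaluated as the algebraic identities they are: a factor with a single
stratum returns q = 0 exactly, and zero total within-stratum sum of squares
returns q = 1 exactly, independent of floating-point cancellation. A
constant outcome (zero global variance) raises an error rather than
returning 0/0.

Continuous factors are discretized by quantiles (default, 5 classes),
equal intervals, or 1-D k-means (a Jenks-style "natural breaks"
optimization). Rasters with fewer distinct values than the requested class
count — binary indicators, already-classified layers — pass through as
categorical factors.

The interaction detector computes q on the cross-classification of the
nonempty stratum pairs. Classification checks the *independent* equality
first with tolerance τ = 1e-9, then nonlinear enhancement (q12 > q1+q2),
bifactor enhancement (q12 > max), nonlinear weakening (q12 < min), and
single-factor nonlinear weakening otherwise; exact boundary ties between
the strict inequalities resolve to the weaker category. Significance
testing of q (noncentral F) is not implemented; the q value itself is the
deliverable.

## Staggered DID

Estimation is ordinary least squares on the dummy-variable form of the
two-way fixed-effects model (unit and year intercepts), which is exact for
balanced and unbalanced panels alike; the test suite checks it against an
independent double-demeaning within-transformation oracle to 1e-8.
Identification requires ≥ 2 units, ≥ 2 years, and both treated and
untreated observations; degenerate panels are rejected, collinear controls
dropped with a warning. Reported fixed effects are centered to sum to zero
with the intercept absorbing their means.

Treatment D_it is binary and absorbing (once infested, always infested),
matching a staggered-adoption design. Because districts differ in infested
area, the preferred specification multiplies D by the district's
treated-host-cell count (`exposure_col`), making β a per-cell annual
effect — the treatment-intensity design of the diffusion literature. An
explicit `area_scaling` constant converts between the coefficient's
reference area and the grid's cell area where the two differ (e.g. a
coefficient quoted per 30 m × 30 m plot applied on a 1-km grid needs
(1000/30)² ≈ 1111 plots per cell); it defaults to 1 and is logged in run
manifests so the scale convention is never silent.

Standard errors are cluster-robust by district (the unit of treatment
assignment); heteroskedasticity-robust variants are available by flag.
Plain TWFE is used deliberately — no Callaway–Sant'Anna-style correction
for heterogeneous staggered effects — because the estimand here is the
homogeneous per-cell coefficient the loss accounting consumes; under
effect heterogeneity the usual TWFE caveats apply.

Counterfactual output is Ŷ(D=0) = Y − β·(treatment regressor), holding all
other terms at observed values, so untreated observations are untouched by
construction. Annual losses are Σ_i (Ŷ−Y)/deflator(t) per sector, with the
deflator indexed to a base year of 1 (defaults to 1 everywhere, i.e.
nominal values); a missing deflator year is an error, not a silent 1.

## Potential-loss projection

Suitability in [0, 1] is partitioned by half-open intervals at thresholds
(0.25, 0.5, 0.75) by default — the value 1.0 and the top threshold belong
to the *high* class. The cut-offs are a conventional quartile-style choice,
configuration-exposed and echoed into output metadata. The projection
assumes a full outbreak over medium-high + high cells: sector loss =
|β| × area_scaling × (eligible cells whose land use is linked to the
sector). 95% bounds map β ± 1.96·SE through the same linear function
(delta method), making interval width exactly 2·1.96·SE·cells·scaling and
the projection exactly linear in |β| and eligible area. Sectors whose
coefficient is not significant at the 5% level are excluded by default.
The total is the exact sum of sector points; its interval combines sector
half-widths in quadrature, treating the sectoral coefficient estimates as
independent (they come from separate regressions on separate outcomes —
an approximation, since the panels share districts and years).

## Spatial diagnostics

Global Moran's I uses queen contiguity, row-standardized, by default;
rook is available. Edge cells keep truncated neighborhoods, the diagonal is
zero, and nodata cells are removed from the weight graph entirely. A
constant field raises an error. A simple one-sided permutation p-value is
provided; full permutation inference and local (LISA) statistics are not.
Kernel density is a plain Gaussian kernel sum at cell centers in per-m²
units, so the surface integrated over the grid recovers the point count
when the bandwidth is small relative to the extent.

## Synthetic scenario generator

The generator emulates the structure of a provincial invasion study:

- **Landscape**: land-use classes carved from a spatially autocorrelated
  field by rank thresholds, so realized shares match the configured
  proportions (default 45% arable, 32% forest, remainder grassland, water,
  urban, bare) to within one cell; districts are Voronoi regions of random
  seed cells (convex, hence contiguous); drivers include a corridor-shaped
  road-density field through the point of entry, a smooth population
  field, and smooth rainfall/slope/altitude/lights/wind surfaces plus
  binary waterway/built-up indicators.
- **Spread**: a deterministic wavefront whose local speed is
  `spread_rate·(1 + corridor_strength·road_density)` cells/year; arrival
  times are geodesic minimum travel times (8-connected, diagonal steps at
  geometric length). Severity is a logistic ramp in years since arrival
  (steepness 1.5, crossing 0.5 half a year after the front). A district's
  first infestation year is the first year any of its cells exceeds
  severity 0.5. Defaults (rate 3 cells/yr, corridor ×4 at full road
  density, entry in the grid's north-west) produce the two-phase clustered
  → contiguous pattern with a share of never-infested control districts by
  the final year. Occurrence points are drawn cell-wise with probability
  proportional to severity and jittered uniformly within the cell.
- **Panel**: Y = α_s + μ_i + γ_t + θ·W_it + β_s·hostcells_i·D_it + ε with
  ε ~ N(0, σ). Planted per-cell effects default to the sectoral loss
  coefficients the DID stage is designed to recover (forestry −0.163,
  cultivation −0.021, husbandry +0.005, fishery −0.034 output units per
  host cell per year) with noise σ = 0.5; district effects are N(0, 5),
  year effects N(0, 2), both centered, and θ = 1.5 on a standard-normal
  climate covariate. All planted values are emitted in machine-readable
  form (TOML sidecar in pipeline runs) for recovery tests.
- **Suitability**: smoothed host-cell density modulated by a mild random
  field, in [0, 1]; a landscape without host cells is entirely unsuitable.

Each generator draws from its own child stream of the master seed
(stable CRC-derived spawn keys), so stages are individually re-runnable
and bit-reproducible.

What the generator does **not** emulate: observation error in infestation
records (reporting lags, under-detection), sampling bias in presence-only
points, serially correlated or spatially correlated panel noise,
anticipation effects or heterogeneous/dynamic treatment effects, economic
spillovers between districts, and land-use change over time. Passing
recovery tests therefore demonstrates the estimator's correctness under
its own assumptions, not robustness to these real-data violations.

## Problem sizes and numerical tolerances

The test suite and acceptance script run at desk scale by design: q-statistic
properties on 20×20 grids (1000 random stratifications), IDW and Moran's I
against brute-force oracles on grids up to 30×30 (1e-9 / 1e-10 agreement),
noiseless DID recovery on 25 districts × 8 years (1e-8), and the
Monte-Carlo recovery study on 100 replicates of 200 districts × 12 years
with σ = 0.5, judged by a 2-Monte-Carlo-SE band around the planted
coefficient and ≥ 90/100 coverage of nominal 95% intervals. The default
end-to-end pipeline (100×100 cells, 50 districts, 12 years) completes in a
few seconds on one CPU. Oracles are kept deliberately naive (double loops,
explicit grouping, double demeaning) and independent of the implementation
paths they check.

## Known limitations

- TWFE under heterogeneous staggered effects can weight cohort effects
  unevenly; interpret β as a homogeneous per-cell effect.
- The sector-total projection interval assumes independent coefficient
  estimates across sector regressions.
- IDW min–max normalization is global per year; a different normalization
  (e.g. per-record-count) would change severity levels but not ranks.
- The dasymetric transform cannot allocate output to districts with zero
  linked land; such mass is flagged, not redistributed.
- Suitability rasters are consumed as given; fitting the upstream species
  distribution model (and its variable screening and tuning) is out of
  scope.
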