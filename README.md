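# invadeloss

Raster-based assessment of the economic losses caused by invasive alien
species, built around the invasion of the fall webworm (*Hyphantria cunea*)
in a provincial agroforestry landscape. The package turns heterogeneous
infestation records and district economic statistics into a causal,
spatially explicit loss estimate, and projects potential losses over habitat
suitability surfaces.

It is aimed at quantitative ecologists and environmental economists who
need a reproducible pipeline rather than a one-off GIS workflow. Everything
operates on a single shared grid (1 km cells by default) and every stage is
driven by one master seed, so full runs are bit-reproducible.

## What it computes

**1. Severity mapping.** Coarse presence–absence records (lists of infested
administrative districts) are reclassified through host-preference weights
on land use, presence-only occurrence points are interpolated by
inverse-distance weighting (r = 1/d², exponent configurable), and the two
layers are combined by a weighted overlay into a per-cell *severity
coefficient* in [0, 1].

**2. Dasymetric disaggregation.** District sectoral gross output
(cultivation, forestry, husbandry, fishery) is distributed onto cells in
proportion to sector-linked land-use weights derived from provincial output
intensities; urban and bare cells are excluded by zero-weight masking, and
a reconstruction check verifies that cell sums reproduce district totals.

**3. Driver analysis (GeoDetector).** The factor detector measures the
spatial stratified heterogeneity a driver explains,

    q = 1 − (Σₕ nₕ σₕ²) / (n σ²),   q ∈ [0, 1],

with population variances over the driver's L strata, and the interaction
detector classifies factor pairs into five categories (nonlinear weakening
… nonlinear enhancement) by comparing q(X₁∩X₂) with q(X₁), q(X₂) and their
sum.

**4. Staggered DID.** Losses are identified by a two-way fixed-effects
difference-in-differences regression on the district × year panel,

    Y_it = α + β·D_it + θ′W_it + μ_i + γ_t + ε_it,

where D_it switches on at each district's first recorded infestation year
(staggered, absorbing). With the treated-host-cell exposure supplied, β is
a *per-cell* annual loss coefficient. Standard errors are cluster-robust by
district. Counterfactual output Y − β·D gives annual, deflator-adjusted
loss series.

**5. Potential-loss projection.** Any external habitat-suitability raster
in [0, 1] is classified into zones; losses from a full outbreak over the
medium-high/high zones are |β| × eligible linked-land-use cells, with 95%
intervals propagated from the coefficient's standard error.

A synthetic scenario generator (`invadeloss.synth`) produces landscapes,
corridor-accelerated spread, occurrence points, suitability surfaces and
economic panels with *planted* ground truth, so the whole pipeline is
testable without any external data.

## Worked example

Run the full synthetic pipeline (100×100 km grid, 50 districts, 2011–2022)
from the command line:

```bash
invadeloss all --out runs/demo --seed 1
```

This writes, among other artifacts, the DID coefficient table
(`did_coefficients.csv`):

```
sector,Estimate,Std. Error,t Value,Pr(>|t|)
cultivation,-0.02067860538,0.0004143493046,-49.90621475,0
fishery,-0.03415731825,0.0004151553775,-82.27598655,0
forestry,-0.1640846867,0.0006038181023,-271.745226,0
husbandry,0.005057129999,0.0004576947543,11.04913253,2.213432939e-28
```

The planted per-cell effects in this scenario are −0.021, −0.034, −0.163
and +0.005 (output units per host cell per year), so the estimator recovers
each sector's coefficient to a few ten-thousandths; forestry is the hardest
hit, consistent with an arboreal defoliator. The driver table
(`geodetector_q.csv`) ranks infestation severity first among the landscape
drivers of output variation (q = 0.232 in this run), and
`loss_projection.csv` converts the significant coefficients into a
potential-loss projection over the suitability map:

```
scenario,sector,point,lower95,upper95,cells
synthetic-baseline,cultivation,93.05372419,89.39916332,96.70828506,4500
synthetic-baseline,forestry,285.6714395,283.6109947,287.7318842,1741
synthetic-baseline,total,378.7251636,374.5297796,382.9205477,6241
```

i.e. a full outbreak over the 6,241 suitable host cells would cost about
379 (95% CI 375–383) output units per year, 75% of it in forestry. Library
use mirrors the CLI:

```python
from invadeloss import ScenarioConfig, fit_staggered_did
from invadeloss.synth import generate_landscape, generate_panel, staggered_schedule

cfg = ScenarioConfig(seed=1)
land_use, admin, drivers = generate_landscape(cfg)
panel, truth = generate_panel(cfg, staggered_schedule(cfg), admin, land_use)
fit = fit_staggered_did(panel[panel.sector == "forestry"],
                        controls=("w_climate",), exposure_col="exposure")
print(fit.beta, truth["beta"]["forestry"])   # -0.16254…  -0.163
```

## Layout

- `src/invadeloss/grid.py` — grid geometry, GeoTIFF/CSV I/O, resampling, overlay
- `src/invadeloss/synth.py` — synthetic scenario generator with ground truth
- `src/invadeloss/matching.py` — severity coefficient construction (PA + PO)
- `src/invadeloss/disagg.py` — dasymetric output disaggregation
- `src/invadeloss/geodetector.py` — factor/interaction detector
- `src/invadeloss/did.py` — staggered two-way FE DID and loss accounting
- `src/invadeloss/spatial_stats.py` — Moran's I, kernel density
- `src/invadeloss/projection.py` — suitability classification and loss projection
- `src/invadeloss/pipeline.py`, `cli.py` — orchestration and `invadeloss` CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
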