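# Methods

## Scope and design

`pastoral` simulates the coupled dynamics of pasture vegetation, grazing
livestock and the soil nitrogen cycle on a raster grid with a daily
timestep.  Its defining design choice is *modularity by concepts*: the
model is not one loop but ~60 component models, each a pure function from
named input concepts to one output concept, grouped into ten thematic
namespaces (moisture, radiation, temperature, vegetation growth,
senescence, litterfall, ingestion, livestock mass, excretion, nitrogen).
A query for any concept is resolved at run time into a directed acyclic
dataflow, executed in topological order, and documented by a DOT graph and
a Markdown report.  Every component can also be evaluated standalone on
stored fields and reproduces its in-dataflow output exactly; the test
suite verifies this, and verifies the whole engine against an independent
monolithic reference loop.

## Context and mediation

A context is a planar grid (row-major, origin top-left; default cell size
50 m) plus an inclusive daily timeline (proleptic Gregorian with leap
days; default 2018-01-01 – 2050-12-31, 12 053 steps).  Inputs on other
grids are mediated on the fly: continuous fields by the area-weighted mean
of overlapping source cells (nodata where valid coverage < 50%),
categorical code rasters by nearest neighbour at cell centres.  A single
planar reference is assumed; there is no CRS reprojection.  Units travel
with every field as a dimension plus a scale to a canonical unit, so
conversions are exact multiplies and dimension mismatches are hard errors.
Climate series coarser than daily would be expanded by step-function
repetition; only daily series are generated and tested.

## Functional forms and why

The limiting factors are deliberately the simplest standard forms with the
required properties (bounded in [0, 1], attaining both endpoints,
monotone/unimodal as appropriate); all shape parameters live in the
per-vegetation-type look-up table so alternatives can be calibrated
without code changes.

* **FT** — trapezoid in daily mean temperature between `t_base`,
  `t_opt_lo`, `t_opt_hi`, `t_max` (°C).
* **FH** — single-bucket soil water `w` with capacity `whc` (mm):
  `FH = min(1, (w/whc)/w_crit)`.  Actual evapotranspiration is
  `min(pet·FH, w + precip)`; overflow beyond `whc` drains.  The balance
  `precip = Δw + aet + drainage` closes exactly by construction.
* **FR** — Michaelis–Menten in the radiation reaching the canopy:
  `FR = rg2/(rg2 + rg_half)`.  `rg2` equals the exposure-adjusted incident
  radiation where the cell's main and overstory codes agree, and 0.2 × it
  under a distinct overstory.  Topographic exposure is a supplied
  multiplicative raster in [0, 1], not a solar-geometry computation.
* **FTRH = FT·FR·FH** — product composition, chosen over `min` because it
  is smooth, symmetric and monotone in each factor; it is ≤ min of the
  three.  **FN is not folded into FTRH**: it applies at actual growth
  (`actual = potential · FN`), keeping climate and nutrient limitation
  separately inspectable.
* **Phenology** `ph` — a per-day-of-year calendar in [0, 1]; the default
  table parameterizes it as a trapezoid over the growing season (ramp from
  day 60, plateau 110–250, end 330).

Potential growth is `xf · FTRH · ph` exactly; `xf` (g·m⁻²·day⁻¹) is the
vegetation type's maximum daily growth.

## Pools and balances

Biomass pools (g DM m⁻²): living, standing dead, litter.  Senescence is
`agb_living · rate · (1 − ph)` (peaking in dormancy), litterfall
`agb_dead · rate`, litter decomposition first-order with the same
FT·FH-modulated rate constant as N mineralization, which preserves the
litter C:N ratio.  Harvest events remove a fraction of living biomass on
given dates and zones; fertilization events add mineral N.

Nitrogen pools (g N m⁻²): soil mineral, litter organic, living tissue,
standing-dead tissue, plus an internal plant reabsorption credit and a
cumulative animal-retained pool.  Mineralization is first-order in litter
organic N times FT·FH.  Plant demand is `potential · n_conc_target`; the
reabsorption credit is spent first and the residual draws on the mineral
pool, defining FN.  Reabsorbed N from senescing tissue (fraction
`reabs_fraction`) buffers the *next* step's demand — same-step buffering
would create an intra-day cycle between senescence and uptake.  Leaching
is `pool_after_uptake · min(1, drainage/whc)`: uptake has priority within
the day so a single Euler step can never overdraw the mineral pool (the
standalone `leaching()` primitive keeps the plain
`pool · min(1, drainage/whc)` form).

Both budgets close exactly (machine precision) every step:
`Δ(living+dead+litter) = growth − harvest − ingestion − decomposition` and
`Δ(all N pools + retained) = fertilization − leaching`; the acceptance
suite asserts ≤ 1e−9 relative over full-year runs.

## Livestock

Cattle and mares are simulated as species-level herds; a per-group
parameter table is aggregated to species means.  Energy is proxied by
digestible dry matter rather than a metabolizable-energy ladder — the
linear surrogate `Δw = conversion_eff · (digestible − maintenance_coeff ·
weight)` preserves the qualitative behaviours that matter (weight loss
under shortage, sensitivity to terrain and availability).  Slope
accessibility declines linearly between species thresholds (cattle 5–25°,
mares 10–35°), so cattle accessibility ≤ mare accessibility everywhere.
Demand is `density · intake_max · accessibility / cell_area`; when summed
demand exceeds the palatable supply, the supply is shared proportionally
to demand (order-independent, equal satisfaction), living biomass consumed
before standing dead.  Ingested N is split into retained
(`n_retention`), solid manure (to litter organic N) and urine (to mineral
N).  Herds are stationary within their distribution rasters.

## Numerical choices

Explicit Euler, Δt = 1 day, matching the daily forcing; no stiffness
arises at the default rates (all first-order constants ≤ 0.03 day⁻¹).
Divisions by pool sizes are guarded at 1e−12 with physically neutral
fallbacks (e.g. N proportion 0 for an empty pool, satisfaction 1 for zero
demand).  Pool updates include a proportional-rescaling primitive that
scales outgoing fluxes when they would overdraw a pool; under the default
parameter tables the constraint `palatability + senescence_rate + harvest
fraction ≤ 1` makes overdraw impossible, so balances close without
rescaling ever triggering.  Dataflow resolution is deterministic: provider
choice uses the scoping order same-namespace > same-project > global from
the perspective of the first consumer that demands a concept, with
lexicographic component-id tie-breaks; topological order is the
lexicographic linearization.  Reading a state field that was never
initialized is a hard error, not a zero default.

## Synthetic landscape

The generator emulates a temperate oceanic mountain rangeland: elevation
100–1200 m (smooth correlated surface; slope by central differences),
nine vegetation types in contiguous patches with a 15% overstory
probability, 14 livestock groups of mixed cattle/mares placed on low-slope
cells, soil water capacity 80–150 mm, and daily climate with a 14 °C
annual mean, ±6 °C seasonal cycle, intermittent gamma-distributed rain
(≈3.5 mm/day annual mean) and radiation 5–21 MJ·m⁻²·day⁻¹ with PET as an
energy-limited proxy (0.2 mm per MJ·m⁻²).  Each artifact draws from its
own named substream of one seed, so outputs are individually reproducible
and byte-identical across runs.

What it does *not* emulate: spatially correlated climate (one series
drives the whole grid), snow, fog and humidity effects, realistic
vegetation community composition, seasonal herd movement, or any real
region's calibrated parameter values.  Passing tests therefore demonstrate
the correctness and internal consistency of the mechanisms — balances,
bounds, modularity, determinism — not predictive skill on real
landscapes, which would require calibration against field data.

## Problem sizes

The test suite exercises 10×10×60-day and 40×40×365-day landscapes for the
conservation and structural suites, and a 5×5×30-day landscape for the
engine-versus-monolithic-oracle comparison at 1e−9 relative tolerance —
sizes chosen so the whole suite completes in well under a minute while
every code path (competition, understory, leaching events, dormancy)
is reached.

## Known limitations

* FTRH's product composition and the trapezoid/bucket/saturation shapes
  are standard but uncalibrated choices; treat `rg_half`, `w_crit` and the
  temperature thresholds as calibration targets.
* No below-ground biomass dynamics (an optional fixed root:shoot fraction
  would be the natural extension), no gaseous N losses, no atmospheric
  deposition or fixation (a constant input term can stand in via the
  fertilization pathway).
* The overstory affects only the radiation pathway (the 0.2 transmission
  rule); shading effects on temperature or moisture are not modelled.
* Livestock demography, milk production and economics are out of scope.
* Components may not observe lagged values of concepts computed later in
  the same step; all cross-day feedback flows through change models.
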