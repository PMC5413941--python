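# Methods

This note documents the models implemented in `geolca`, their assumptions,
the defaults that matter, and what the synthetic test landscapes do and do
not establish about real data.

## Scope and design stance

The package compares two ways of attributing land-use-change impacts to a
product: a linear, volume-invariant LCA branch, and a predictive branch in
which a land-change model selects the converted cells and spatially
explicit impact models are differenced across the change. Every spatial
model here is a deliberately simple, *monotone* variant of the
corresponding family of ecosystem-service models (delivery-ratio,
edge-effect, fragmentation models): simple enough that each mechanism is
independently testable against hand arithmetic and brute-force oracles,
while preserving the qualitative behaviours the comparison depends on —
buffering, fragmentation, and volume-dependence of marginal land quality.
They are not calibrated reimplementations of any released model suite, and
no result here should be read as a site-specific prediction.

## Raster substrate

Grids are square-celled, row-major, origin at the upper-left; areas are
`cell_size²` in m², reported in hectares. Nodata cells are excluded from
every statistic. Co-registration of all grids in a run is checked, never
silently fixed by resampling; pre-aligned inputs are a requirement.
I/O supports ESRI ASCII grids and single-band TIFF, with grid metadata
carried in the TIFF ImageDescription tag as JSON; both round-trip
bit-exactly.

Terrain uses single-direction D8 routing. Depressions are removed by
priority-flood filling with an epsilon gradient, which guarantees every
valid cell a strictly descending path to the grid edge; steepest-descent
ties are broken in the fixed neighbour order E, SE, S, SW, W, NW, N, NE.
Streams are cells whose flow accumulation reaches `stream_threshold`
(default 50 cells; a configuration choice, since stream definition is
scale-dependent). A cell's *downslope path* is the chain of cells strictly
between it and its receiving stream cell (or the edge) — exactly the cells
whose vegetation can intercept material leaving it.

## Synthetic landscapes

The generator emulates the statistical structure of a coarse-resolution
agricultural region: smooth correlated soil and climate fields (Gaussian
random fields: white noise convolved with a Gaussian kernel and
re-standardized, so moments are exact and autocorrelation scales with the
correlation length), a tilted rough DEM that drains to one edge, and —
the core contract — agriculture drawn per pixel as
`Bernoulli(logistic(β·z))` with *known* coefficients on standardized
predictors (pH, slope, %silt, %clay, soil organic matter). Because the
generating process is known, the land-change model is validated by
parameter recovery rather than by eyeballing maps. Default cell size is
500 m (25 ha cells), matching the coarse land-cover products such
pipelines typically start from; 200×200 cells give ~40,000 observations,
enough for coefficient recovery well within 3 standard errors.

Non-agricultural cells are split into forest/savanna/grassland by a second
latent field honouring the requested class proportions, with urban, water
and barren sprinkled at their proportions. Riparian vegetation is painted
over natural cells within `riparian_width` cells of a stream; it is
derived from stream geometry, so it is *not* an entry in
`class_proportions`. The agriculture fraction is governed by the logistic
intercept, so the `class_proportions` agriculture entry is honoured only
when the caller sets the intercept consistently (`logit(fraction)` for
moderate slopes). Yields increase with a soil-quality index plus noise;
attainable yield is current yield times one plus a spatially varying gap,
so it never falls below current.

What the synthetic landscapes do **not** emulate: real spatial
covariance between soils, climate and land use; mixed input resolutions;
multi-year dynamics; crop rotation; anthropogenic drivers (roads,
markets) of conversion. Passing tests therefore demonstrate internal
correctness and mechanism, not predictive skill on any real region.

## Demand and partition

Crop demand is HDPE tonnage times the conversion-chain product
(HDPE → ethylene → ethanol → crop). The chain defaults (1.0, 1.74, 3.0)
are round placeholders, not inventory-sourced values. Intensification
closes a fixed fraction (`closure_fraction`, default 0.2) of the per-cell
yield gap on existing agriculture; its supply fills demand first, trimmed
largest-gap-first (with the marginal cell scaled) when capacity exceeds
demand, so `intensification + expansion = demand` holds to 1e-6 t and
expansion demand is monotone non-increasing in the closure fraction.
A single interpretable knob was chosen over region-specific trend
calibration, which would not be identifiable from the data the package
generates.

## Land-change model

The suitability model is a maximum-likelihood logistic regression
(statsmodels) of the agriculture indicator on standardized predictors,
fitted over non-excluded valid cells; the fitting region's means and
standard deviations are stored on the model and reused at prediction, so
fit and predict are a consistent pair. Zero-variance predictors are
dropped from the optimization and reported with coefficient 0 and
infinite standard error; perfect separation is flagged with a warning
rather than treated as fatal. Cells that cannot convert (urban, barren,
water) are excluded from the regression and can never be allocated.

Allocation is deterministic rank allocation: convertible cells sorted by
descending suitability (row-major index breaks ties) convert until
cumulative production — yield × area, so demand is met in tonnes, not
hectares — first meets demand. Total production therefore lands in
`[demand, demand + one cell)`. A relative tolerance of 1e-9 on the
stopping comparison prevents an exact-fit demand (re-running an allocator
at its own production) from converting one spurious extra cell.
Determinism makes the greedy selection equal to brute-force top-k
selection and makes converted sets nested across increasing demand, both
of which are tested; a probability-weighted stochastic mode was
considered and rejected as untestable against an exact oracle. The
proximity allocator is the same greedy contract with suitability replaced
by negative Euclidean distance to current agriculture.

## Impact models

**Carbon.** Per-cell stock is the class carbon density (a single pooled
t C/ha value). With edge effects enabled, forest cells hold
`density × (θ + (1−θ)(1−exp(−d/d₀)))` where `d` is distance to the
nearest non-forest cell — a two-parameter saturating form (defaults
θ = 0.6, d₀ = 500 m) chosen so monotonicity in depth and the interior
asymptote are testable. Stock change converts at 44/12 t CO₂ per t C and
is amortized over `amortization_years` (default 20, the PAS2050-style
convention), in both branches; whether to amortize or report pulse
emissions is exposed rather than hard-coded.

**Sediment.** Gross erosion is USLE `R·K·LS·C·P`. R is a linear
erosivity proxy (0.5 × annual precipitation), K a texture/organic-matter
surrogate clipped to [0.02, 0.65], LS the classic quadratic slope-percent
approximation — all three stand in for locally calibrated inputs and can
be replaced by supplying the grids directly. Export is
`USLE × ∏(1 − retention_eff)` over the downslope path, computed in one
ascending-elevation sweep (linear cost). This retention chain preserves
the property the analysis hinges on: removing a vegetated buffer between
a source cell and the stream strictly increases export, and total export
never exceeds gross erosion. It is not a calibrated connectivity-index
delivery model.

**Nitrogen.** Class surface loads (kg N/ha/yr), plus intensification
loads, routed through the same retention chain with nitrogen-specific
efficiencies. Export is linear in load at fixed landscape (superposition
is tested). Intensification responses are linear: 20 kg N/ha applied per
t/ha of yield increment, 25 % of application leached, 30 mm irrigation
per t/ha — placeholder slopes of plausible magnitude for an intensive
cereal system.

**Blue water.** Irrigation only: `max(0, Kc·ET₀ − P_eff)` on irrigated
agricultural cells (effective precipitation is a fixed 0.7 fraction of
annual precipitation), at 10 m³ per mm·ha, plus intensification
irrigation. Newly converted cells are treated as irrigated by default
(config flag); existing agriculture's baseline irrigation cancels in the
before/after difference and is not counted.

**Biodiversity.** Per-cell MSA is `MSA_LU` for non-natural classes and
`MSA_LU × MSA_F(patch area)` for natural ones, with patches found by
8-connectivity across all natural classes jointly and the fragmentation
multiplier read from an area-threshold table (defaults 0.55 / 0.70 /
0.85 / 0.95 up to 10 / 100 / 1,000 / 10,000 ha, then 1.0 — plausible
placeholders, not sourced estimates). No infrastructure or encroachment
pressures are modelled. Damage is the MSA-weighted area lost between two
landscapes summed over *all* cells, so patch shrinkage and bisection on
unconverted land contribute without special-casing; conversion of natural
land can never increase landscape-total MSA·ha.

## LCA integration

The spatial branch substitutes the model deltas for the agricultural
stage: amortized ΔCO₂e plus fertilizer-production GWP
(5.6 kg CO₂e per kg N applied, configurable) for GWP; ΔN export for
eutrophication; Δsediment export for erosion; irrigation consumption on
new plus intensified agriculture for water; MSA·ha lost for biodiversity.
Non-agricultural stages (ethanol, ethylene, polymerization) enter both
branches as identical per-tonne constants from config — placeholders, as
the package models the agricultural stage only. Erosion in the standard
branch is occupation-based gross erosion without delivery, mirroring the
"total soil erosion on land" convention it comparators use; biodiversity
is potential-natural-vegetation MSA minus current MSA times occupation.

A *degeneracy bridge* ties the branches together: on a homogeneous
landscape (uniform soils, climate, yields, planar terrain, one source
class, retention and fragmentation and edge effects off),
`matched_standard_factors` derives the standard factors analytically from
the class table, and the two branches must agree to 1e-6 relative. Any
difference between them on a real landscape is therefore attributable to
spatial heterogeneity, not to bookkeeping.

Sensitivity uses two-corner evaluation: each parameter's monotone
direction per category is probed one-at-a-time around the central run,
then the per-category low/high corners are evaluated (evaluations cached
across categories). For models monotone in each parameter this equals
full 2^k corner enumeration, which is tested on toys; it is cheaper than
factorial or Monte-Carlo designs and matches an upper/lower-bound error
bar framing. Non-monotone interactions would not be bracketed.

Validation runs the logistic and proximity allocators at the production
volume implied by an observed t0→t1 conversion and tabulates per-tonne
impacts with ratios to the observed branch. When t1 was itself produced
by one of the allocators, that allocator's ratios are exactly 1 — a
self-consistency guarantee of the deterministic contract, used as the
harness's fixed point.

## Numerical choices and degenerate inputs

* Pit-fill epsilon: 1e-7 of the DEM's elevation span (1 if flat), enough
  to orient flats without distorting slopes.
* Allocation and trimming tie-breaks: row-major index, always.
* Empty demand returns empty change maps and zero partitions; demand
  beyond convertible capacity is an error naming the shortfall; a
  single-class response or misaligned stack is an error, never a warning.
* Zero-volume scenarios report zero per-tonne impacts (the per-tonne
  quantity is undefined at volume 0).
* Intensification supply uses exact partial credit on the marginal cell,
  so conservation holds to float precision, not just to one cell.

## Problem sizes

Shipped defaults are sized for a laptop: 200×200 cells (≈1 M ha at 500 m
resolution) for landscape-level contracts, 80×80 for end-to-end checks,
≤20×20 for brute-force oracle comparisons. The full test suite and the
reproduction script each complete in seconds; all stochastic tests are
seeded.

## Known limitations

* One crop, one region, one time step; no displacement, trade, price
  response, or indirect land-use change.
* Delivery models are uncalibrated monotone variants; absolute export
  magnitudes are only as good as the R/K/LS and retention inputs.
* Default class-table, fragmentation, response-slope and conversion-chain
  values are internally consistent placeholders for synthetic runs, not
  sourced inventories; real analyses must replace them.
* The standard and spatial branches share amortization and
  non-agricultural constants by construction, so comparisons isolate the
  land-change and spatial-model substitution only.
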