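# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `mangrove-slr`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## ²¹⁰Pb CF-CS dating

The constant flux–constant sedimentation model treats atmospherically
delivered ("excess") ²¹⁰Pb as arriving at a constant rate onto a surface
aggrading at a constant rate V, so excess activity decays exponentially
with burial depth: `excess(l) = excess(0)·e^(−d·l)`, `V = λ/d`.

Choices and rationale:

* **Excess** is total ²¹⁰Pb minus ²²⁶Ra per interval, evaluated at the
  interval midpoint (cm, positive downward) — the conventional support
  point for interval-sampled cores.
* **Fit** is ordinary least squares of `ln(excess)` on midpoint depth.
  Non-positive excess intervals are dropped (the log is undefined there
  and intervals at supported background carry no decay signal); their
  count is reported. A fit needs at least `min_points` = 5 usable
  intervals, and a non-negative fitted slope raises an error rather than
  returning a meaningless rate.
* **λ defaults to 0.03 yr⁻¹**, the value conventionally printed for
  ²¹⁰Pb in this application, although ln 2/22.3 ≈ 0.0311 yr⁻¹; λ is a
  parameter everywhere it is used, so either convention can be supplied.
* **Uncertainty**: the confidence interval for d is the regression
  slope's t-interval (default 95 %); the interval for V maps the d
  endpoints through the monotone reciprocal `V = λ/d`. This is exact at
  any n, avoiding the asymmetry error a delta-method interval would
  introduce at small sample sizes. Under the generator's multiplicative
  lognormal noise, `ln(excess)` is exactly Gaussian-linear in depth, so
  the nominal 95 % coverage is exact by construction — the Monte-Carlo
  coverage test in the suite checks calibration of the implementation,
  not of an approximation.
* The identity `V·d = λ` holds to machine precision for every fit and is
  asserted as a property.

## Water masking and shorelines

* The water index is `green + red − NIR − SWIR1` on integer reflectance;
  a pixel is water when the index **strictly** exceeds T = 500 (the
  printed threshold on the 0–10000 surface-reflectance scale; an index of
  exactly 500 is land).
* Isolated inland water (aquaculture ponds, lakes) is removed by keeping
  only the water components 8-connected to the sea — by default every
  component touching the raster's seaward (northern) edge, or a
  user-supplied seed cell. This replaces manual visual interpretation
  with a deterministic, testable rule. 8-connectivity is used so
  diagonal tidal-creek pixels stay connected.
* The shoreline is the set of shared edges between 4-adjacent water/land
  cell pairs, merged into polylines and georeferenced through the grid's
  affine transform. With square cells the total length is exactly
  (number of water/land 4-adjacencies) × cell size, which is also the
  independent oracle the tests use. Cell-edge tracing was chosen over a
  marching-squares contour through cell centres because only the former
  makes lengths exact in cell units (a half-plane boundary across an
  N-column raster measures N·cellsize, not (N−1)·cellsize).
* Edge migration casts transects normal to the old edge (every 60 m by
  default), intersects them with the new edge, and signs the nearest
  crossing positive landward. Displacements within ±15 m (half a 30 m
  cell) classify as `stable`; transects that miss the new edge within
  the 5 km search window report NaN and `missing`.

## Scenario table and rates

* The built-in table stores relative sea-level rise (cm above the year
  2000) for RCP 2.6/4.5/8.5 at 2030/2050/2100 at the 5/17/mean/83/95 %
  quantiles. Levels between anchor years are linearly interpolated —
  with only three anchors, any smoother curve would be an invention —
  and extrapolation outside [2030, 2100] is refused.
* Average rates are `level_cm × 10 / (year − rate_origin_year)` in
  mm yr⁻¹ with **rate_origin_year = 2005**: this origin reproduces every
  tabulated mean rate exactly (650/95 = 6.84, 310/45 = 6.89, 180/25 =
  7.2, …), whereas the levels themselves are relative to 2000. Both
  epochs are separate, configurable fields, and the pipeline manifest
  records them so reports are self-describing.
* Local land subsidence (1.09 ± 3.22 mm yr⁻¹) is carried as metadata and
  **not** added to levels, on the reading that the tabulated values are
  already *relative* sea level; a user who reads them otherwise can add
  it explicitly.
* Survival-threshold flags compare rates strictly against 6.1 mm yr⁻¹
  ("likely" exceeded) and 7.6 mm yr⁻¹ ("extremely likely" exceeded).

## Inundation model

* **H0 selection.** Candidate contours are drawn (marching squares on
  the DEM) at every multiple of the contour interval (default 0.1 m)
  within the DEM's range. The seaward boundary of the mangrove mask is
  the set of mask cells 4-adjacent to a lower-lying non-mask cell; the
  contour minimising the mean distance from those boundary-cell centres
  to its vertices is selected and its level taken as current mean sea
  level. A flat DEM has no contour and errors; a contour interval much
  coarser than the mask relief still returns the nearest coarse level,
  with a warning when the winning contour sits more than three cells
  from the boundary.
* **ΔH₂₀₀₀₋₂₀₁₈** defaults to 8.28 cm — the observed local rate of
  4.6 mm yr⁻¹ applied over the 18-year span — because the observed
  cumulative value is not published; it is configurable and recorded in
  the manifest as an assumption.
* **Accretion span** T = N − 2018 by default: H0 is read from a
  present-day surface, so accretion accrues from the present, not from
  the scenario baseline 2000. The reference year is configurable.
* **Va field.** Each mangrove cell takes the rate of its nearest core
  site in grid coordinates (Voronoi assignment). How a handful of cores
  should represent a whole forest is genuinely open; nearest-station
  assignment is the simplest defensible rule and is flagged in the
  manifest.
* **Loss rule.** A mangrove cell is lost when elevation < H, strictly:
  cells exactly at H survive, consistent with a seaward fringe sitting
  "at mean sea level or slightly above". With per-cell Va the comparison
  is equivalent to testing the accreted surface (elevation + Va·T)
  against the no-accretion water level. The default is a pure bathtub;
  `connectivity="sea-connected"` restricts losses to cells 8-connected
  to the sea through sub-H terrain, and always yields a subset of the
  bathtub loss.
* Reported `h_future_m` per quantile uses the mask-mean Va as a
  representative scalar (the loss itself is computed cellwise).
* Areas are cell counts × cellsize² / 10⁴, in hm² (hectares);
  lost + surviving = total exactly by cell accounting.

## Synthetic sites

The generator emulates exactly the features the analysis is sensitive to:

* **DEM** = inclined plane (offshore minimum at the northern, seaward
  edge to inland maximum) + a Gaussian-smoothed random field (amplitude
  `dem_roughness_m`, default 0.05 m) + sinusoidal tidal creeks carved
  strictly below mean sea level, entering from the seaward edge and
  tapering out ~70 % of the way inland. Defaults: 120×120 cells at 30 m
  (the resolution of the elevation and reflectance products the pipeline
  targets), elevations −1 to +3 m, MSL 0.40 m, MHWS 1.20 m.
* **Mangrove band**: cells with MSL ≤ elevation ≤ MHWS, the elevation
  range the habitat occupies between its seaward and landward bounds.
* **Reflectance**: water pixels (open water below MSL, plus ponds) get
  high green/red and low NIR/SWIR1 means; land the reverse; the
  noise-free water index is +4600 vs −3700, far either side of T = 500.
  Additive Gaussian noise (default σ = 150 counts) perturbs each band;
  values are rounded and clipped to [0, 10000]. `noise_sd = 0` makes the
  entire site deterministic — reflectance *and* DEM microtopography — so
  noise-free fixtures reproduce generator truth exactly; this single
  switch is the package's own design choice.
* **Ponds**: 2×2 blocks on dry land kept ≥2 cells from any open water
  (and from each other), so 8-connectivity can never bridge them to the
  sea; the inland-water filter must remove exactly `pond_count`
  components.
* **Cores**: excess = `surface_excess·e^(−d·l)` at interval midpoints
  with multiplicative lognormal noise of unit median and chosen
  coefficient of variation; ²²⁶Ra background is exact and total ²¹⁰Pb =
  excess + background, keeping activities non-negative. Default station
  slopes are d = 0.03/0.53 and 0.03/0.40 cm⁻¹, i.e. the generating rates
  equal the two field-measured Dongzhaigang rates, with a default of
  80 Bq kg⁻¹ surface excess over 20 Bq kg⁻¹ background, 2 cm intervals
  to 60 cm depth — typical magnitudes for estuarine mangrove cores.

What the generator does **not** emulate: real hypsometry (the ramp's
area–elevation curve is nearly linear, unlike a natural floodplain),
tides and waves, vegetation spectral mixing, compaction, spatially
correlated reflectance noise, and datum error between the DEM and local
mean sea level (the fixture defines MSL in the grid datum, sidestepping
the vertical-datum problem a real SRTM analysis faces). Passing tests
therefore demonstrate correctness of the computational chain, not
real-site loss magnitudes — which is why absolute published loss areas
are covered through percentage arithmetic and closed-form ramp
hypsometry rather than simulated.

## Problem sizes and determinism

Synthetic sites in the tests are 40–120 cells on a side; the inundation
oracle sweep uses fifty 100×100 random fields; parameter-recovery uses
500 replicate cores of 30 intervals. These sizes put every quantity the
suite asserts well past its convergence scale while keeping the whole
suite near interactive speed. All randomness flows from
`numpy.random.default_rng(seed)`; a fixed seed reproduces every raster
bit-for-bit and every CSV byte-for-byte, which the pipeline test
asserts.

## Published-value cross-checks

Two derived constants reconcile the published tables internally:
`rate_origin_year = 2005` (above), and a total mangrove area of
**1841 hm²**, with which every published loss area/percentage pair is
simultaneously consistent to two decimals (489 → 26.56 %, 589 →
31.99 %, 302 → 16.40 %), whereas the 2019 mapped total is printed as
1842 hm². Both constants are carried; `paper_tables_report` (and the
`report` CLI subcommand) recomputes the full rate block and percentage
block against either denominator and flags any cell outside its printed
precision.
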