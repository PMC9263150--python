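# mangrove-slr

Will a mangrove forest keep pace with the sea? A mangrove wetland survives
rising water only while its soil surface accretes vertically at least as
fast as relative sea level rises; where it cannot, the seaward fringe
drowns and the habitat band is squeezed against dykes and ponds on the
landward side. `mangrove-slr` implements the full computational chain used
to ask that question for a macro-tidal embayment such as Dongzhaigang
(Hainan, China), and ships a seeded synthetic-site generator so the whole
chain runs and is tested without any satellite or field downloads.

The pipeline has four scientific stages:

1. **²¹⁰Pb CF-CS sediment dating.** Excess ²¹⁰Pb (total ²¹⁰Pb − ²²⁶Ra)
   decays with burial depth as `excess(l) = excess(0)·e^(−d·l)` under
   constant flux and constant sedimentation. Ordinary least squares of
   `ln(excess)` on depth gives the slope `d` (cm⁻¹), and the vertical
   accretion rate is `V = λ/d` with λ = 0.03 yr⁻¹.
2. **Spectral water masking and shorelines.** A pixel is water when
   `green + red − NIR − SWIR1 > T` (T = 500 on the 0–10000
   surface-reflectance scale). Inland ponds and lakes are removed by
   keeping only water 8-connected to the sea, and the shoreline is traced
   along water/land cell edges. Low-edge migration is measured along
   transects (positive displacement = landward retreat).
3. **Scenario projection.** A built-in table of relative sea-level-rise
   quantiles (cm above 2000) for RCP 2.6/4.5/8.5 at 2030/2050/2100 yields
   levels, average rise rates (`rate = level×10 / (year − 2005)` mm yr⁻¹),
   and flags against the mangrove survival thresholds of 6.1 ("likely")
   and 7.6 ("extremely likely") mm yr⁻¹.
4. **Bathtub inundation.** The future water level in the DEM datum is
   `H = H0 − ΔH₂₀₀₀₋₂₀₁₈ + ΔH₂₀₀₀₋N − Va×T`, where H0 is the elevation
   contour nearest the mangrove's seaward boundary and Va the per-cell
   accretion rate (nearest-station Voronoi field from the dated cores).
   A mangrove cell is lost when its elevation is strictly below H; losses
   are reported in hm² (hectares) and percent, per scenario, year, and
   quantile.

## Worked example

```python
from mangrove_slr import (SiteConfig, make_site_fixture, dating_report,
                          extract_water_mask, select_h0_contour,
                          SeaLevelContext, build_accretion_field,
                          scenario_matrix, results_table,
                          builtin_scenario_table)

fx = make_site_fixture(SiteConfig(seed=1), core_noise_cv=0.1)
report = dating_report(fx.cores, known_rates={"LS": 0.41, "DX": 0.64})
print(report[["station", "v_cm_per_yr", "r_squared", "source"]].round(3))

wm = extract_water_mask(fx.image)
print(f"inland water bodies removed: {wm.removed_components}; "
      f"shoreline length: {wm.shoreline_length_m/1000:.1f} km")

h0, _ = select_h0_contour(fx.dem, fx.mangrove_mask, contour_interval=0.1)
ctx = SeaLevelContext(h0=h0, delta_h_2000_2018=8.28,
                      accretion_reference_year=2018)
rates = dict(zip(report["station"], report["v_cm_per_yr"]))
field = build_accretion_field({s: rates[s] for s, _, _ in fx.core_sites},
                              fx.core_sites, fx.mangrove_mask)
results = scenario_matrix(ctx, builtin_scenario_table(), field,
                          fx.dem, fx.mangrove_mask)
table = results_table(results)
sel = (table["year"] == 2100) & (table["quantile"] == "mean")
print(table[sel][["scenario", "h_future_m", "lost_area_hm2",
                  "lost_pct"]].round(2).to_string(index=False))
```

prints

```
  station  v_cm_per_yr  r_squared      source
0      HG        0.509      0.994         fit
1      SJ        0.393      0.996         fit
2      LS        0.410        NaN  literature
3      DX        0.640        NaN  literature
inland water bodies removed: 3; shoreline length: 13.4 km
scenario  h_future_m  lost_area_hm2  lost_pct
  RCP2.6        0.59          46.80     19.90
  RCP4.5        0.69          80.37     34.18
  RCP8.5        0.90         144.99     61.65
```

Reading this: the two synthetic cores (generated with 10 % multiplicative
activity noise) date to 0.51 and 0.39 cm yr⁻¹ against generating rates of
0.53 and 0.40; the three aquaculture ponds planted by the generator are
removed from the water mask; the H0 contour selection recovers the site's
mean sea level (0.40 m); and by 2100 the mean projected water level sits
0.19–0.50 m above H0 depending on scenario, drowning 20–62 % of this
synthetic site's mangrove band. The loss percentages for the synthetic
site are *not* those of a real embayment — its hypsometry is a simple
ramp — but every arithmetic step between them and the inputs is.

The same chain runs from a shell:

```sh
mangrove-slr run-all --seed 1 --out runs/demo
mangrove-slr report            # computed vs published table arithmetic
```

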