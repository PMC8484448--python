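# rodentmap

Mapping the vegetation impact of vole and lemming population peaks from
paired-year, UAV-scale multispectral imagery.

Rodent peaks in Arctic tundra remove field-layer vegetation in patterns that
are invisible to satellites and impractical to survey on foot: cleared
patches of 0.3–1 m around burrows, narrow under-snow runways, and diffuse
thinning, intermingled with untouched ground at sub-metre scale. With
~0.1 m multispectral imagery from two consecutive summers — one at the
population peak, one after — the impact becomes mappable as a localized
NDVI loss. `rodentmap` is a tested, reusable implementation of that
analysis for ecologists and remote-sensing scientists:

- **NDVI change detection**: NDVI = (NIR − R)/(NIR + R) per year,
  nearest-neighbour co-registration, ΔNDVI = NDVI₁ − NDVI₀.
- **Scenario-based impact mapping**: a pixel is impacted when
  ΔNDVI ≤ τ (τ ∈ [−0.10, −0.04]) and its habitat is not masked; *best*,
  *minimum* and *maximum* scenarios bracket the estimate; impact fractions
  are reported per habitat class and per study area.
- **Object-based land cover**: mode-seeking segmentation at ~0.3 m and
  random-forest classification of segments, with out-of-bag error, overall
  accuracy and Cohen's κ.
- **Ground-truth protocol**: 2 m × 2 m plots scored in 400 quadrants of
  0.1 m for bite marks, feces, runways and burrows (0–1600 points), OLS
  validation of plot scores against plot-mean ΔNDVI, and the trapping
  catch rate (individuals per 100 trap nights).
- **Spatial statistics**: raster Moran's I (rook/queen, binary/row
  weights) and empirical semivariograms fitted with the double-exponential
  model γ(h) = c₀ + c₁(1 − e^(−h/a₁)) + c₂(1 − e^(−h/a₂)).
- **Ecosystem upscaling**: NDVI → GPP/biomass via monotone exponential
  models, relative-change summaries, and the Jensen gap
  E[f(NDVI)] − f(E[NDVI]) that quantifies how coarse pixels hide
  heterogeneous browning.
- **Synthetic scenes**: a first-class generator of paired-year scenes with
  known per-pixel impact truth (habitat mosaic, nests/runways/thinning,
  sensor noise, illumination drift, co-registration jitter), so the whole
  chain is testable end-to-end without any survey data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run a complete synthetic study area (256 × 256 pixels at 0.12 m, 10%
true impact) and summarize it:

```bash
rodentmap report --out demo --seed 0 --grid-size 256
```

```
 area  impact_best_pct  impact_min_pct  impact_max_pct  mean_ndvi_year0  mean_ndvi_year1  ndvi_change  ndvi_change_pct  gpp_change_pct  biomass_change_pct  morans_i  max_variogram_range_m
area1        13.021411        8.297596       19.047849          0.59819         0.575865    -0.022325        -3.732055       -8.867413          -10.420202  0.790308               3.255388
```

Reading the row: the true impacted fraction (10%) lies inside the
[min, max] = [8.3%, 19.0%] scenario bracket; the best estimate (13.0%)
overshoots slightly because the simulated 2-px co-registration error adds
false positives at habitat boundaries — the artefact the min/max scenarios
exist to contain. Scene-mean NDVI drops by 0.022 (−3.7%), which the convex
property models amplify to −8.9% GPP and −10.4% biomass. The mapped impact
is strongly clustered (Moran's I 0.79) with spatial autocorrelation out to
~3.3 m — nest/runway clusters, not salt-and-pepper noise. `demo/` also
receives the per-area variogram figure and the summary as CSV.

The same stages are available as library calls (`simulate_habitats`,
`simulate_impact`, `render_scene_pair`, `compute_ndvi`,
`coregister_nearest`, `ndvi_change`, `run_scenarios`, `morans_i`,
`empirical_variogram`, `fit_variogram`, `validate`, `jensen_gap`, ...) and
as CLI commands (`simulate`, `ndvi`, `coregister`, `classify`, `detect`,
`validate`, `stats`, `report`) operating on GeoTIFF/GeoJSON/YAML files.

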