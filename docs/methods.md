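# Methods

`rodentmap` implements the analysis chain used to map the vegetation impact
of a vole/lemming population peak from paired-year, UAV-scale multispectral
imagery, together with a synthetic-scene generator that provides known
per-pixel truth so every stage can be tested quantitatively without survey
data. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Detection model

Rodent herbivory removes field-layer vegetation, browning the surface:
near-infrared reflectance falls and red rises, so NDVI = (NIR − R)/(NIR + R)
drops. Impact is mapped per pixel from the change raster

    dNDVI = NDVI(year 1) − NDVI(year 0),

with a pixel counted as impacted when dNDVI ≤ τ for a negative threshold τ
and the pixel's habitat class is not masked. The year-0 raster is first
resampled onto the year-1 grid by nearest pixel centre (ties toward the
lower index), which is the resampling that such surveys use to reduce
co-registration artefacts without resorting to fine-registration.

Because the threshold-and-mask choice is judgemental, three scenarios
bracket the estimate:

| scenario | τ (NDVI) | masked classes | role |
|---|---|---|---|
| best | −0.07 | water | headline estimate |
| min | −0.10 | water, birch forest, wetland, snowbed, meadow | conservative bound |
| max | −0.04 | water | permissive bound |

τ is constrained to the plausible band [−0.10, −0.04]; the comparison is
inclusive. Water is always masked. The min scenario masks the classes where
an apparent NDVI loss is most plausibly an artefact rather than herbivory:
birch forest (field-layer impact hidden or mimicked under a canopy),
wetland and meadow (inter-annual surface-moisture variation of moist
graminoid ground), and snowbed (NDVI strongly tied to melt timing, which
shifts between years). This mask list is a package default, deliberately
conservative, and fully overridable per scenario; with a narrower min mask
the min scenario is not reliably below the true impacted fraction once
residual misregistration contributes false positives (see "Nuisance
magnitudes" below).

Impact fractions are reported per habitat class (impacted pixels / class
pixels) and in total (impacted pixels / non-water, non-nodata pixels); an
empty class yields an undefined (NaN) fraction, never 0. The scenario runner
enforces |τ_max| ≤ |τ_best| ≤ |τ_min|, nested masks, and checks the
resulting min ≤ best ≤ max bracketing on every run.

## Synthetic scenes

The generator emulates the study system: ~0.12 m pixels over a mosaic of
eight tundra land-cover classes plus water, a baseline peak-season scene and
a following-year scene with impact, and the sensor nuisances that make
change detection hard.

**Habitats.** A Gaussian random field smoothed to a configurable correlation
length (default 6 m) is quantile-thresholded into the configured class
proportions, giving spatially coherent patches with exact areal shares. With
smoothing disabled the labels are i.i.d. — a useful degenerate case because
neighbour agreement then has the closed form Σ p². Quantile thresholding of
a single field orders classes along the field value, so class adjacency is
not independent (e.g. water tends to border the same classes); none of the
downstream statistics depend on the adjacency structure. Three additional
smoothed fields stand in for the topographic covariates (elevation, wetness,
vegetation height) a real classification would use.

**Impact truth.** Three morphologies are placed on susceptible classes
(water and barren are never susceptible) until the impacted pixel count
reaches the target fraction of the non-water area (default 0.10):

- *nests*: discs of 0.3–1 m diameter at points drawn with
  susceptibility-weighted probability; removal intensity 1.
- *runways*: correlated random walks emanating from nest centres
  (persistence 0.85, step 2 px, length 2–10 m, width 0.15 m); intensity 1.
- *thinning*: elliptical patches of 0.8–2.5 m radius with fractional
  intensity (default 0.5), emulating diffuse clipping.

The element stream is drawn independently of the target, so increasing the
target only extends the same element sequence — realized impact is monotone
in the target and nested across targets at fixed seed. The final element is
trimmed rim-inward (farthest pixels from its centre first, keeping it
contiguous) so the realized count matches the target exactly. The relative
prevalence of the three morphologies (default 30/30/40 by the placement
mix) is a configuration choice, not calibrated to field data.

**Rendering.** Within each class, baseline NDVI is the class mean plus a
shared smooth anomaly field (correlation length 2 m) times the class sd. R
and NIR are reconstructed from NDVI at constant class brightness
s = R + NIR (so NDVI is exact by construction); G and RE take class
baselines. Year 1 repeats the same vegetation state with impacted pixels'
NDVI lowered by `ndvi_depression × intensity` (default depression 0.3),
then band noise, an illumination gain/offset, and a constant-offset
co-registration shift of the pixel content (georeference unchanged) are
applied. Reflectances leaving [0, 1] are clipped with a warning.

**Nuisance magnitudes.** The survey this emulates used reflectance-panel
calibration, so the illumination drift must be a residual, not a raw
between-day difference: gain 0.98, offset 0.002 reflectance. An offset of
0.005 would already bias scene-mean NDVI by ≈ −0.015 on its own — larger
than most of the scene-level NDVI changes such surveys report — so the
defaults were anchored to keep the non-impact bias a small fraction of the
printed change magnitudes (−0.004 to −0.027). Band noise is 0.005
reflectance (orthomosaics average many overlapping frames), and the
co-registration error is a 2 px content shift, matching the "mostly within
2–3 px" registration quality of such data. Under these defaults the shift
is the dominant error source, contributing ~2% false positives concentrated
at habitat boundaries and displaced impact rims — the overestimation
artefact the scenario bracketing exists to contain.

**Closure.** With all nuisances off, unimpacted pixels are bit-identical
between years and every impacted pixel's dNDVI is exactly
−depression × intensity, so thresholding recovers the truth fraction
exactly for any |τ| ≤ depression × min intensity (0.15 at the defaults —
hence exact closure at the best-estimate τ = −0.07). For |τ| between
depression × min intensity and depression, thinning pixels would be missed;
the often-quoted "any |τ| < depression" form of this property assumes
unit intensity everywhere.

## Land-cover classification

Segmentation aggregates the scene to a ~0.3 m working resolution by block
mean (factor 2 on 0.12 m pixels), then runs iterative joint-domain mode
seeking with flat kernels: each working pixel moves to the mean of the
window pixels (spatial radius 1.5 m) within `range_radius` (0.02
reflectance, Euclidean over bands) of it spectrally. Mixed boundary pixels
converge to the nearer class mode, sharpening boundaries. Connected
components of spectrally similar 4-neighbours become segments; segments
below `min_size` merge into their spectrally closest neighbour, iterated to
a fixed point. An optional `max_segment_size` intersects large components
with a spatial block grid — the spatial-bandwidth counterpart of the joint
kernel — so a classifier gets several training segments per class instead
of one per contiguous patch. Exact equivalence with any particular OBIA
toolbox is not a goal; the contract is behavioural (homogeneous halves give
two segments, constant scenes one, the size floor holds, and synthetic
scenes are recovered at OA ≥ 0.9).

Segments are classified by a random forest (200 trees, seeded) on
per-segment mean band/NDVI/covariate features; accuracy is reported as the
out-of-bag error plus a confusion matrix, overall accuracy OA = trace/total
and Cohen's κ = (OA − p_e)/(1 − p_e) from the OOB predictions. κ ≤ OA holds
identically. Training labels in the synthetic experiments are per-segment
majority votes of the simulated habitat map, standing in for manually
digitised training areas; pixel-level OA against the simulated map is then
bounded above by segment purity (~0.95), which is why the recovery
criterion sits at 0.9 rather than higher.

## Ground-truth protocol and validation

A field plot is 2 m × 2 m, scored on a 20 × 20 grid of 0.1 m quadrants
(400 per plot). Four impact categories — bite marks, feces, runways,
burrows — are flagged independently per quadrant, one point each, so scores
range 0–1600. The survey simulator assigns each quadrant its majority truth
label and mean intensity, then flags each category with probability
(base detection probability given the label) × intensity; the base matrix
is a configuration default, not calibrated. Plot pairs follow the field
design: impacted plots centred on plot-scale impact density above the 85th
percentile, controls on impact-free ground, both restricted to the most
representative habitats. The trapping index is 100 × individuals /
trap-nights.

Validation regresses plot score on plot-mean dNDVI (pixel centres inside
the footprint) by OLS, pooled and per habitat stratum. The calibrated
analogue of the published pooled fit draws scores from the paired design
(controls ~ U(0, 60), impacted ~ U(150, 900)) and sets the dNDVI noise so
the score–dNDVI correlation is −0.735, i.e. a population r² of 0.54; the
sampling distribution of r² at n = 40 then has sd ≈ 0.09, which is what the
"± 0.1 over replicates" check probes. Under score shuffling the OLS r² has
expectation 1/(n − 1).

## Spatial statistics

**Moran's I** uses the cross-product statistic
I = (n/S0) Σ w_ij z_i z_j / Σ z_i² with rook or queen contiguity, binary or
row-standardized weights (default queen/row; the scheme is carried in the
result so outputs are self-describing). Nodata pixels are excluded from n
and the weights. A constant raster raises rather than returning 0. The
implementation is validated against an exhaustive O(n²) weight-matrix
evaluation on all grids up to 20 × 20.

**Variograms** are estimated from a random pixel sample (default 100,000,
without replacement) with γ(h) = (1/2N(h)) Σ (z_i − z_j)² binned at 0.3 m
lag width. All pairs within `max_lag` are enumerated via a KD-tree; when
the expected pair count exceeds `max_pairs` (default 2 × 10⁶) the pixel
sample is thinned to the size whose all-pairs count fits the cap —
additional pixels add no information at a fixed pair budget, and an
unthinned enumeration at the 100,000-pixel default needs tens of gigabytes.

The model fitted is the double exponential

    γ(h) = c0 + c1 (1 − e^(−h/a1)) + c2 (1 − e^(−h/a2)),

by weighted least squares (weights = pair counts) with nonnegative sills.
Two identifiability constraints are imposed: range parameters are bounded
below by the lag width (below the binning resolution an exponential term is
indistinguishable from nugget, which would make a flat pure-nugget
variogram unidentifiable) and above by the maximum sampled lag, with sills
capped at five times the largest binned semivariance (otherwise a huge-sill,
huge-range term chases finite-domain drift in the far bins). The effective
range of a component is 3a (95% of its sill). Two summaries are derived:
`dominant_range`, the effective range of the larger-sill component (the
right estimator when the field has one true structure, used in the recovery
experiments), and `max_range`, the largest effective range among components
holding > 1% of the total sill — the interpretation adopted for the
"maximum variogram range" summary, recorded in output metadata since the
quantity has no single standard definition. On fields simulated with known
exponential covariance (circulant embedding, so the truth is exact), the
dominant effective range is recovered with ≈ −4% aggregate bias over 20
seeds at 256², with ~12% per-seed sampling scatter at 8,000-pixel samples.

## Ecosystem scaling

GPP and biomass are estimated from NDVI by monotone regression models,
default exponential f(x) = α e^(βx) with shape-only parameters (α = 1;
β = 4.8 for GPP, 5.9 for biomass). These are not calibrated to any
published site regression; they are chosen so that, at tundra NDVI ≈ 0.6,
relative changes amplify in the order |biomass %| ≥ |GPP %| ≥ |NDVI %|
(the amplification of a mean shift δ is ≈ βδ against a relative NDVI change
of δ/mean, i.e. a factor β × mean NDVI ≈ 3–3.5). Relative change is
100 × (mean₁ − mean₀)/mean₀ over the shared valid-pixel mask excluding
water, which avoids composition bias from differing nodata.

The Jensen gap quantifies the sub-pixel heterogeneity effect: for an
aggregation factor b, the coarse estimate applies f to b × b block-mean
NDVI while the fine estimate averages per-pixel f(NDVI). For convex f and
any non-constant raster, coarse < fine — estimating GPP from coarse
(satellite-scale) NDVI systematically underestimates the contribution of
heterogeneous disturbance. Linear models commute with averaging exactly,
and the implementation reports that identity exactly rather than
accumulating summation-order round-off. Thin rasters (fewer rows or columns
than the factor) tile along the remaining axis; otherwise edge remainders
are truncated.

## Problem sizes and determinism

The test suite and the acceptance script run everything on 256 × 256 scenes
(≈ 30 m × 30 m at 0.12 m pixels), 8,000–20,000-pixel variogram samples, 20
field-recovery seeds and 100 validation replicates — sizes at which every
statistic is stable at the tolerances tested while the whole suite runs in
well under a minute. All randomness flows from per-stage generators keyed
as (seed, stage), so a configuration reproduces bit-identical scenes,
truth, and downstream products.

## Limitations

- The generator has hard class boundaries, a single constant co-registration
  offset, and spatially white band noise; real orthomosaics have smooth
  local warps, vignetting/BRDF structure, and textured vegetation. Passing
  the recovery tests shows the chain is correct and well-conditioned under
  these conditions, not that the thresholds would be optimal on real
  imagery.
- Scenario thresholds and mask lists are defaults, not calibrated to any
  real site; per-area overrides are configuration.
- The detection-probability matrix of the plot survey and the morphology
  mix of the truth generator are plausible but uncalibrated; validation
  results on synthetic data test internal consistency of the protocol, not
  field detectability.
- The NDVI→GPP/biomass models are shape-only stand-ins for published
  site-specific regressions; only relative changes and orderings are
  meaningful, never absolute flux or biomass values.
- Variogram ranges beyond the sampled maximum lag are unidentifiable by
  construction; `max_range` is bounded by the sampling window.
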