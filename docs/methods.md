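# Methods

This note documents the models and procedures `uavyield` implements, the
choices made where the published record is open, and what the synthetic
scenarios do and do not establish.

## Raster handling and plot extraction

Rasters are GeoTIFFs restricted to the subset the pipeline needs: a
north-up affine georeference (ModelPixelScale + ModelTiepoint), an EPSG code
in the GeoKey directory, and GDAL's nodata tag. Pixel data go through
tifffile. Plot boundaries are GeoJSON polygons; Shapefile input is not
supported. A pixel belongs to a plot iff its **center** lies inside the
polygon — an any-overlap rule would make per-plot pixel counts, and hence
the area fractions behind CC and LI, ambiguous. CRS disagreement between
plots and raster is an error, never a silent reprojection. An optional
inward buffer (`plot_shrink`) discards plot-border pixels, since how plot
rectangles were delineated on the imagery (full plot vs buffered interior
rows) is generally a survey-protocol decision.

## Radiometric calibration

Empirical-line calibration per band and per acquisition date. The five
candidate families are fixed as

    linear a·x+b, quadratic a·x²+b·x+c, exponential a·e^{b·x},
    logarithmic a·ln x + b, power a·x^b

(the family names are standard; the functional forms are the package's own
fixing of them). Polynomial and log-linearisable families are fitted in
closed form; exponential and power fits are refined by Levenberg–Marquardt
on the original scale so that r² is always compared on reflectance, not on a
transformed axis. Families whose domain is violated (log/power with
non-positive DN, exponential/power with non-positive reflectance) are
skipped. Selection is by maximum r² on the fitting pairs; ties within 1e-9
break toward fewer parameters, then toward the fixed family order — so an
exactly linear relation is reported as linear even though the quadratic
matches it. At least three distinct-DN tarps are required (five families, up
to three parameters).

## Canopy features

**Spectral indices.** The thirteen index formulas are implemented exactly as
published, including two deliberate literalisms: OSAVI uses the denominator
(NIR − R + L) with L = 0.16 (the canonical OSAVI uses NIR + R + L; a
`osavi_canonical` switch restores it), and TCARI multiplies only its second
term by RE/R. Zero-denominator pixels become NaN, are excluded from plot
means, and are counted in the run manifest. A registry allows extra indices
to be added without touching the pipeline.

**Structure.** Canopy/soil segmentation thresholds CIVE inclusively on
[−28, 5]; the interval and the RGB DN scale it presumes are paired
configuration values. CC is the canopy-pixel fraction of the plot, stored in
[0, 1]. CHM = DSM − DEM on a shared grid; negative values (surface
reconstruction noise) are clamped to zero and counted. CH defaults to the
mean CHM over canopy pixels, configurable to a percentile (p95) or all-pixel
mean; a plot with no canopy pixels falls back to the all-pixel mean with a
warning rather than failing.

**Texture.** GLCM statistics use N = 64 equal-width grey bins over the
band's valid range, offset (1, 1), a symmetric matrix normalised to sum 1,
and a 7×7 window truncated at image edges; a co-occurrence counts when both
endpoints of the offset pair fall inside the window. All three parameters
are configuration keys, since co-occurrence software differs in its
defaults. Correlation divides by the product of the two marginal standard
deviations, which keeps COR in [−1, 1]; a degenerate single-grey-level
window is defined as COR = 1. Textures are computed per RGB band with
band-suffixed feature names; the default model input uses only the green
band to limit collinearity. Plot aggregation is the mean over all valid plot
pixels for spectral and texture maps and the canopy-masked mean for CH;
both aggregation masks are configurable, as the choice between all-pixel
and canopy-only averaging is a genuinely open one.

## Lodging index

The class raster (NL/LL/SL; upright, 30–60° leaning, near-ground) is an
input — the pixel classifier that produces it from imagery is outside this
package's scope. Area fractions are pixel-count fractions over valid pixels
(all pixels share one area on a regular grid), nodata excluded from
numerator and denominator. LI = Σ LDᵢ·Sᵢ. The numeric codes LD are not
standardised; the default (0, 1, 2) makes a fully upright plot score 0,
which matches the reading that a larger index means more lodging. The codes
are configurable (e.g. (1, 2, 3)); LI is affine-covariant in them, so the
choice shifts and scales, but never reorders, plots.

## Yield model

One random forest per growth stage (VT, R3, R5 — tasseling, milking,
denting), never pooled. Defaults: 100 trees, random seed 15, trees grown
until leaves are pure or below the minimum split size (2), all features
considered at each split, bootstrap resampling. The split takes
round(0.8·n) training rows by a seeded permutation (132 plots → 106/26) and
evaluation is on the held-out rows; a flag allows all-data evaluation for
diagnostics. The coefficient of determination is the standard
1 − Σ(ŷ−y)²/Σ(y−ȳ)²: a printed variant that squares (ŷᵢ − ȳ) instead of the
residual is not a residual sum and is not implemented. rRMSE is RMSE over
the mean observed test yield, in percent. Variable importances are
normalised impurity reductions. No feature screening is performed.
The residual-vs-LI diagnostic regresses (predicted − observed) on LI over
the evaluation split and reports the slope plus over/under-estimation counts
by LI tercile; a positive slope means lodged plots are overestimated.

## Synthetic scenarios

The generator emulates a 132-plot field trial (grid of ~3 m × 10 m plots at
0.4 m GSD, a variety block and a nitrogen block) observed at three stages.
Per plot, a latent vigor v ~ U(0.2, 1) drives: canopy reflectance (NIR up,
red down with v), canopy cover (Bernoulli per pixel around 0.45 + 0.5v),
canopy height (0.4 + 2.4v m, scaled 0.85/0.95/1.0 at VT/R3/R5), and an RGB
appearance whose green dominance keeps canopy CIVE inside [−28, 5] and soil
outside it. Lodging affects ~60 % of plots; SL and LL fractions are Beta
draws and classes are laid out as jittered distance-ordered patches — blob
shape is arbitrary because LI provably depends only on fractions. Digital
numbers are obtained by inverting a known per-band transfer law (one of
each of the five families), and tarp pairs come from the same inversion.
Yields follow

    yield = 2000 + 11000·v − 1500·LI + N(0, 500) kg/ha, floored at 500,

spanning roughly 1,300–13,800 kg/ha, the magnitude of real multi-variety
maize trials; the floor keeps rRMSE well-defined. All randomness flows from
one seed through named sub-streams (vigor, canopy, lodging, per-stage raster
noise, tarps, yield), so identical seeds give bit-identical files and
individual artifacts can be regenerated independently.
`make_feature_table` is a fast path that evaluates the indices on each
plot's mixture-mean reflectance instead of rendering rasters; it is used
where many model replicates are needed (its indices differ slightly from
pixel-wise means because the indices are nonlinear, which is irrelevant to
the model comparisons it serves).

What the scenarios do **not** emulate: atmospheric and BRDF effects, mixed
pixels at canopy edges, SfM reconstruction artifacts, within-plot fertility
gradients, classifier error in the lodging raster, and any correlation
between lodging severity and vigor. Passing tests therefore show the
pipeline's internal correctness and the recoverability of a known signal,
not field-scale accuracy.

## Problem sizes and numerical choices

The test suite runs scenario work at 12–24 plots and the model studies at
the default 132 plots with 20 replicate seeds; the acceptance script runs
the full raster pipeline once at 132 plots and the replicate studies at
n = 20, sizes at which every check completes in well under a minute each on
one core. Ties in calibration r² are resolved at 1e-9; GLCM variance below
1e-12 triggers the degenerate-correlation convention; lodging fractions must
sum to 1 within 1e-6 on input and reproduce to 1e-9 internally. Determinism
is exact: fixtures, split membership and forest predictions are bit-identical
under a fixed seed.

## Known limitations

- GeoTIFF support covers the north-up affine subset only (no rotated grids,
  tiled pyramids, or projected-CRS parameter parsing beyond the EPSG code).
- The windowed GLCM is a per-pixel Python loop over bincounts — exact and
  fast at plot scale, not meant for whole-orthomosaic texture maps.
- Only GeoJSON plot boundaries are read; Shapefiles must be converted first.
- The lodging classifier is out of scope; classification error propagates
  into LI untreated.
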