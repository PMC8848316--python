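# Methods

## The measurement model

A gradient-phenotyping run observes, for each pot *i*, a red:blue
photon-flux ratio `r_i` measured at the pot's position and a set of
phenotypic descriptors `y_i` extracted from 6 side-view and 1 top-view RGB
frames. For every descriptor, species and imaging day the package fits

    y_i = a + b · ln(r_i) + ε_i            (ordinary least squares)

and summarizes the response as an **effect size**: the difference between
the fitted predictions at the extreme ratios, as a percentage of the
prediction at the minimal ratio,

    effect % = 100 · (ŷ(r_max) − ŷ(r_min)) / ŷ(r_min).

The regression is performed in natural log; the predictions, hence the
effect %, the Pearson correlation and the p-value are invariant to the log
base (only the slope's units change; it is reported per ln unit). The
p-value is the two-sided t-test of the slope, which for simple OLS is
numerically identical to the test of the Pearson correlation. Significance
categories use strict inequalities (NS, p < 0.05, p < 0.01). No
multiple-testing correction is applied by default; a Benjamini–Hochberg
option (`fdr=True`) adds adjusted p-values for users screening many
descriptor × day cells.

Choices a user can change:

* **Effect-size baseline** — the denominator is the prediction at the
  *minimal* ratio by default (reads as "% change when moving from the most
  blue-enriched to the most red-enriched position"); `baseline="max"` or
  `"mid"` are available. A non-positive baseline prediction makes the
  percentage undefined and is reported as NaN, never as 0.
* **Ratio extremes** — taken from the *observed per-species* ratios, since
  species occupy different rows of the room and therefore sample slightly
  different ratio ranges; a global range can be forced.
* **Confidence interval** — delta method on (intercept, slope) with a
  t(n−2) quantile. Its 95% coverage is verified by simulation in the test
  suite.
* Degenerate inputs: constant descriptor values give slope 0 with p = 1
  (no evidence of effect); constant ratios are a hard error; fewer than 3
  finite pairs are rejected.

## Morphometry conventions

Descriptors are computed per view from a binary plant mask with a
mm-per-pixel calibration, then aggregated (max for HeightMax/WidthMax,
mean for AreaMean and all per-view shape/color factors; Voxel =
√(max side area · min side area · top area), mm³).

* **Region perimeter** uses the 4-direction Crofton estimate. Naive
  pixel-edge counting overestimates perimeters of smooth shapes so badly
  that the isoperimetric quotient 4πA/P² of a disk is ~0.90 at any radius;
  with Crofton the digitized-disk circularity is 1.004 at r = 100 px and
  converges to 1 (tested).
* **Convex hull, Feret diameters** are computed on the exact convex polygon
  of the foreground pixel *corner* points. The hull then contains every
  foreground pixel square, so solidity ≤ 1 holds structurally, and hull
  area/perimeter and rotating-calipers Feret extremes agree with
  independent computational-geometry references to machine precision.
  MeanFeret is the mean of the max and min Feret diameters.
* **Fitted ellipse** is the moment-equivalent ellipse (same area and second
  central moments as the pixel region).
* The 0–1 shape factors (roundness, solidity, convexity, compactness) are
  capped at 1.0: discretization can push the raw ratio marginally above 1
  for convex regions (Crofton slightly underestimates axis-aligned
  straight edges, so convexity of a digitized square would read ~1.06).
  Circularity is reported uncapped, as its convergence to 1 from above is
  itself a diagnostic of the perimeter convention.
* **Hue statistics** are linear mean/SD on the 0–255 hue channel
  (HueCv = 100·SD/mean). No circular statistics are used; a hue
  distribution straddling the red wrap point is flagged
  (`hue_wrapped`), not corrected. "Mean grey value" for integrated density
  is (R+G+B)/3 over foreground; integrated density = foreground pixel
  count × mean grey.
* **Chlorophyll estimate** uses per-pot mean channel values (not per-pixel
  evaluation then averaging), like GLI and TGI.
* Multi-plant pots are one specimen: segmentation keeps all connected
  components above a minimum area (default 25 px), and hull/ellipse are
  computed on their union.
* Empty masks are returned flagged, never raised, so a plant-free frame
  skips the pot rather than aborting a batch.

## Imaging chain

Side views photograph a dark plant in front of a diffusive back-lit white
background; top views a lit plant over black cloth. Segmentation therefore
defaults to Otsu thresholding of inverted brightness (side) and of excess
green 2G−R−B (top); fixed thresholds can be configured, and rectangular
regions (e.g. the color chart) can be excluded. White balance applies
per-channel gains equalizing the neutral chart patch's channel means
(idempotent within rounding; clipped to [0, 255]); spatial calibration is
physical patch size / detected pixel size. Segmentation is insensitive to
the global linear gains white balance applies (verified: IoU change < 0.01).

## The synthetic experiment generator

The generator emulates the study design the package targets, and its
defaults are the conditions under which the statistical guarantees are
verified:

* **Layout** — rooms of 12 columns × 10 rows; each species occupies 3
  contiguous rows (36 pots), except the compact rosette reference, which
  gets 4 rows (48 pots) because only its top view is informative.
  Replicates are randomized within each species block once at treatment
  start. Pot UIDs encode room:row:column.
* **Light map** — 5 LED clusters spanning the columns, set-points
  log-spaced between the gradient endpoints (default 0.1–10, two decades
  symmetric about 1; the endpoints are configurable stand-ins, as is the
  5-cluster geometry). ln(ratio) interpolates piecewise-linearly between
  cluster centers, so it is monotone across columns before per-pot
  measurement noise (log-normal, SD 0.05 on ln ratio). Total PPFD is held
  in a 100–150 µmol m⁻² s⁻¹ band (center 125, SD 8, clipped).
* **Morphotypes** — parametric species stand-ins with a habit (rosette,
  caulescent, bush, grass), asymptotic size, baseline descriptor values and
  a monomolecular growth curve (35% of asymptotic size at treatment start,
  time constant 12 d). Every programmed gradient response is linear in
  ln(ratio): value = baseline·(1 + E(day)/100 · u), with u the position of
  ln(ratio) within the gradient span, so the programmed percentage E(day)
  *is* the quantity the effect-size regression estimates. E(day) follows a
  gamma-shaped rise–peak–decay pulse (transient responses and
  post-treatment relaxation); decay 0 gives a sustained ramp-and-hold.
  Noise: mean-preserving multiplicative log-normal on dimensions (default
  CV 10%), additive Gaussian on color channels (SD 3, clipped to [0, 255])
  and shape factors (SD 0.02, clipped to (0, 1]). The default seven
  morphotypes use overlapping foliage-green colors deliberately: with
  realistic palettes, color descriptors alone give only partial species
  separation and the full descriptor set discriminates best.
* **Rendering** — procedural 2.5-D: a stem/blade skeleton plus leaves at
  fixed 3-D azimuths, projected at 30° steps for the 6 side views and
  vertically for the top view, drawn without anti-aliasing on the
  view-appropriate background (default 200×200 px at 2 mm/px). The returned
  ground-truth masks mark exactly the generated plant pixels, and the
  ground-truth descriptor table is computed from those masks, so the
  rendered route validates segmentation + measurement end to end. A plant
  exceeding the frame raises an error rather than being clipped.
* **Schedule** — twice-weekly imaging days over a 31-day treatment by
  default (10 sessions); treatment end is carried into the analysis so
  post-treatment sessions are flagged.

Two paths share this parameterization: full rendering (for pipeline
validation) and a direct descriptor-table simulation (for statistical
validation at scale — effect recovery, CI coverage, type-I error, PCA —
where rendering thousands of scenes would add nothing). What the generator
does **not** emulate: leaf texture, specular highlights, occlusion by pot
or neighbours, lens distortion, photoperiod/irradiance confounds, or any
mechanistic physiology. Passing tests therefore demonstrate correctness of
the *computational* chain under known truth, not robustness to real-world
imaging artifacts.

## Multivariate discrimination

PCA runs on z-scored descriptor columns (correlation-matrix scaling — the
scale mix of mm, mm², %, and unitless factors makes covariance scaling
meaningless). Components are sign-fixed by orienting the
largest-magnitude loading positive. Species separation is scored by the
mean silhouette coefficient on the first two components; pairwise species
silhouettes are also reported. Rows with missing values in the selection
are dropped; constant columns are dropped with a warning. The
`exclude_side_for` option blanks side-view descriptors of species whose
side views are uninformative (flat rosettes), which removes those species
from side-including selections — mirroring how such species are reported
as NA in side-view analyses.

## Problem sizes used in validation

The validation suite uses 36-pot single-species blocks for regression
checks (200 replicates per programmed effect level, 1000 null replicates),
a 36-pot × 9-session rendered experiment for the end-to-end comparison,
and the full 7-morphotype, 264-pot layout over three late-treatment days
for the PCA comparison — the natural block sizes of the emulated design.

## Known limitations

* Linear hue averaging is wrong for red-dominant material (wrap-around);
  flagged, not corrected.
* The effect-size percentage is undefined when the baseline prediction is
  ≤ 0 (can occur for strongly negative slopes on small-valued
  descriptors); such cells are NaN in the effects table.
* The delta-method CI assumes homoscedastic residuals; multiplicative
  noise makes residual SD grow with the mean, which is mild at CV 10%
  (coverage stays within the tested 0.95 ± 0.03 band) but would degrade
  for much noisier descriptors.
* Dose-response is modelled as linear in ln(ratio) throughout; thresholds
  or non-monotone responses would call for nonlinear models, which are out
  of scope.
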