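# Methods

This note records the models, parameter choices and numerical decisions
behind `corebreak`, and what the synthetic validation does and does not
establish about real field imagery.

## Imaging model and geometry

The instrument photographs a 40-well cassette (5 columns × 8 rows, 45 mm
wells) holding the forty 5 cm segments of one 2 m soil core, at roughly
13 px/mm (an 18-megapixel frame).  The default `CassetteLayout` reproduces
this geometry: well radius 290 px, pitch 640 px, portrait frame
3456 × 5184.  All analysis happens after 2× block-average downsampling
(`downsample_factor`), which doubles the signal-to-noise ratio of the weak
fluorescence signal; reported lengths are in downsampled pixels
(`length_mm` converts using `px_per_mm / downsample_factor`).

Tests and simulations run on proportionally scaled layouts
(`CassetteLayout.default(scale)`), typically at scale 0.3–0.5.  Roots and
debris keep their *absolute* pixel sizes (they are physical objects, not
cassette features), so scaled scenes are geometrically valid as long as the
wells remain much larger than the debris — true from scale ≈ 0.35 up.  The
acceptance-style suites use scale 0.35 with fifty scenes/templates, sizes
chosen so the full suite completes in a few minutes on one core.

## Well segmentation

* Background suppression is a connected-component (attribute) filter:
  bright components are kept when their moment-ellipse elongation
  (semi-major / semi-minor axis ratio) is below 1.2 and their area lies in
  `[0.5, 2.0] × π r²` of the expected well radius; everything else is
  flattened to the median background level.  Retained components keep their
  grey values unchanged (contour preserving), which also makes the filter
  exactly idempotent: a second pass re-detects precisely the same
  components.
* The automatic threshold is computed from the joint distribution of grey
  level and gradient magnitude: the grey histogram is restricted to pixels
  whose Sobel gradient magnitude is below its median (mode interiors, away
  from blurred edges) and a two-class variance-maximising split (Otsu) is
  applied to that restricted sample.  This is a concrete realisation of
  bivariate grey/gradient thresholding; the variant used by the original
  instrument is not published, and agreement is asserted at the level of
  behaviour (edge-blur-insensitive global threshold), not algorithm
  identity.
* Each well component's circle model uses the centroid and the semi-major
  axis of the moment-based best-fit ellipse, restoring a circular footprint
  for wells distorted by edge flare.  Raster labelling clusters centres
  into rows by *y* (tolerance = median fitted radius, with a running row
  mean) before sorting by *x*, so ±2 px jitter cannot scramble the 1–40
  ordering.

## Ridge detection

The detector is Steger-style: Gaussian-derivative Hessian at scale
`ridge_sigma` (default 2.0 downsampled px, matched to the ~2–4 px
downsampled root width), ridge strength = −λ₋ (the more negative Hessian
eigenvalue), cross-ridge direction from the corresponding eigenvector
(computed with the better-conditioned of the two algebraic eigenvector
forms, per pixel).  Directional non-maximum suppression compares each pixel
with its two bilinearly interpolated neighbours along the cross-ridge
direction.  Hysteresis keeps weak ridge pixels (response ≥ `ridge_low`,
default 0.5) only when connected to strong ones (≥ `ridge_high`, default
2.0).  Two post-passes stabilise the centreline:

* gap bridging: binary closing with a radius-1 disc followed by
  re-skeletonisation, healing 1–2 px dropouts along a chain without
  merging structures more than ~4 px apart;
* endpoint retraction: smoothing extends a ridge a few pixels past the true
  end of a structure, so endpoint pixels are removed while their response
  is below `ridge_end_fraction` (default 0.4) of their own chain's
  90th-percentile response.  The threshold is relative, so faint and bright
  roots are trimmed alike.

Chains shorter than 3 px are discarded as sensor noise.  The default
response thresholds were set empirically against the synthetic scenes, as
the original system's were against field images; both are exposed in
`PipelineParams`.  Monotonicity of the mask in the thresholds holds for the
core detector (no gap bridging); the bridging/retraction passes trade exact
monotonicity for count stability.

## Debris exclusion

Debris (straw, lint) is distinguished purely by thickness.  The polygonal
structuring element is an octagon of circumradius `max_root_radius_px`
(default 4 downsampled px ≈ 0.6 mm root radius; the original value is
unpublished).  The attribute rule for the background image keeps components
with elongation < 5 **or** area > 0.25 × well area — the reading under
which the background-removed image isolates exactly the thick, elongated
objects.  The grammatically ambiguous published form ("elongation less than
five times the length over the width") is implemented as
elongation := length/width with threshold 5.  Subtraction floors at zero
before the fixed threshold of 50 grey levels.

Two deliberate consequences, visible in the tests: debris that is compact
(elongation < 5, e.g. two crossed straws merging into one blob) or very
large (> 0.25 × well area) stays in the background and is *not* flagged as
debris — the rule targets exactly the linear, root-like contaminants that
could be miscounted.  Before subtracting the mask from the linear
structures it is dilated by `debris_dilate_px` (default 4 px, the detector
scale): the ridge the detector traces along a debris *edge* can fall a few
pixels outside the exact thickness mask, and the margin removes those edge
ridges too.

## Association and measurement

Reconstruction is binary morphological reconstruction (components of the
debris-excluded mask that intersect the wells-masked seeds), 8-connected
throughout.  Each object is assigned to the well with the largest pixel
overlap, ties to the lower label; one object is never counted in two wells.

Component length is estimated by connecting the centreline pixels into a
minimum-spanning tree over the 8-adjacency graph (weights 1 / √2, which
drops the phantom diagonal links at staircase corners), decomposing the
tree into simple chains between endpoints and branch points, resampling
each chain every 4 pixels, and summing the Euclidean polyline length.  On
ideal straight strokes of known length this estimator is within ~2–6 %
across orientations; plain √2-weighted link counting overestimates by up to
25 % on the same input.  Colour filtering uses the downsampled RGB: circular
mean hue must lie in `blue_hue_range_deg` (default 170–290°), mean HSL
lightness above 40/255, and chain length strictly above 10 downsampled px.
These three filter values are not published ("empirically determined"); the
defaults were chosen against the synthetic scenes and are all exposed.

A frame is flagged dim when the mean downsampled blue intensity falls below
`dim_mean_threshold` (default 8/255).  The flag is computed from the image,
not read from camera metadata, and is carried into every CSV row so dim
frames can be analysed separately.

## Synthetic scenes: what they emulate, and what they do not

The generator renders: dark, low-chroma soil background with gentle
large-scale texture (soil is non-fluorescent); roots as anti-aliased
strokes whose transverse profile `1 − (d/r)²` is strictly maximal at the
centreline (guaranteeing a unique ridgeline), drawn with butt caps so the
rendered extent equals the recorded polyline arc length; debris as thick
flat-topped capsules; additive zero-mean Gaussian sensor noise clipped to
[0, 255]; and dim frames as a 0.04× exposure scaling applied before the
noise.  Random roots are smooth constrained walks inside their well disc
(curvature radius ≥ ~40 px), kept ≥ 24 px from each other and from debris
so the ground-truth per-well count is unambiguous; requested lengths come
from a 120–200 px range, never below 48 px.

These choices make the ground truth *decidable*, which is what the
end-to-end guarantees (exact per-well counts, ≤ 10 % length error, zero
debris-induced detections, < 0.05 false positives per empty well at noise
SD ≤ 5) are defined against.  Real break faces violate several of them:
roots cross and overlap (merged counts are then expected and correct by
design, but ground truth is no longer the rendered-root count), root
brightness varies along the root and with age/health, soil can carry
smeared fluorescent residue, and fragment surfaces are uneven.  Passing the
synthetic suite therefore demonstrates the correctness of the *mechanism*,
not field-level accuracy; field deployments should re-run the calibration
workflow per site and species, as the calibration module supports.

## Calibration model

The simulated campaign draws, for each internal break plane (every 5 cm of
a 2 m core) and each of its two faces, a count with mean `gain × RLD(z)`
(Poisson by default; `noise="none"` for deterministic rounding).  The
default depth profile is `1.5 · exp(−z/45 cm)` cm/cm³ — a typical cereal
RLD decline — with per-core log-normal variability (σ = 0.3).  Washed RLD
is measured on 10 cm increments; the window rule pairs increment
(*t*, *t*+10) with the summed counts at *t*, *t*+5 and *t*+10 cm, adjacent
windows sharing their boundary depth by construction.  The two opposing
faces at one break plane are *summed* (a pulled root shows on exactly one
face, so the sum counts it once); `mean` and `max` are available for
sensitivity analysis.  With summation the expected windowed count is
`6 × gain × RLD`, the slope the recovery tests check.  Pearson correlation
(not rank) matches the least-squares calibration context.  Field
correlations depend on the unavailable original field data and are out of
scope; the recovery tests instead verify the statistical machinery against
the generator's known model, using the Monte-Carlo distribution of r over
replicate campaigns as the reference band (median of 5 campaigns tested
against the 95 % band, which keeps the false-alarm probability of the test
itself negligible).

## Cost model

Throughput is cores/day ÷ (7 h × team size), reported to 2 decimals; cost
per core is wage × people × hours ÷ cores/day at US$34.22/h.  Percentages
are reported half-up as integers with exact rationals retained
(`*_exact`): the 4-person ratio is exactly 86.67 % (prints 87) and the
total-campaign ratio ≈ 89.3 % (prints 89); the corresponding published
table prints 86 and 88, consistent with truncation or an intermediate
rounding that is not recoverable, so comparisons allow ±1 point on those
two cells.  The 16 % labour-efficiency gain is computed from the 2-decimal
reported rates (4.29/3.71), matching how the published figure arises.  One
push press (US$40 000) and one imaging box (US$5 000) serve both sites, as
site harvests are non-concurrent.

## Known limitations

* Overlapping or crossing roots are counted as one object; no attempt is
  made to split them.
* No correction of lens/barrel distortion — only tolerance to it via the
  circle refit.
* Sub-pixel centreline localisation and per-root width are not estimated.
* The bivariate threshold and the ridge detector are behavioural stand-ins
  for unpublished commercial components; parameters are exposed rather
  than canonical.
* Compact or very large debris is deliberately outside the debris rule (see
  above); colour-based debris classification is not attempted.
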