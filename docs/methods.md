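# Methods

This note records the models implemented in `turfcam`, the conventions and
defaults chosen where the problem admitted more than one reasonable answer,
and what the synthetic generators do and do not emulate.

## Imaging model and color conversions

All processing is at 8-bit sRGB depth; 16-bit TIFF input is reduced by
dropping the low byte.  Conversions are purely colorimetric — no camera
profile or white-balance estimation is attempted, on the assumption that
exposure control and any color correction happen upstream of the metrics.

HSV follows the hexcone model with the integer storage convention common in
8-bit pipelines: hue in half-degree units 0–179 (round-half-up, wrapping at
180), saturation and value 0–255.  The classification thresholds are
integers on exactly this scale, which is why it is the storage convention.
Conversion math runs in floating point and only the stored raster is
quantised, so index computations never double-round.  Achromatic pixels
carry hue 0 with saturation 0; nothing downstream branches on hue when
saturation is zero.

CIELAB uses the sRGB companding curve, D65 white and the 2° observer
(delegated to scikit-image; validated in the tests against an independent
hand-written sRGB→XYZ→Lab implementation to ΔE\*ab < 0.1).

Chromatic coordinates are r = R/(R+G+B) etc.; pure-black pixels have no
chromatic coordinates and are excluded from index means rather than mapped
to a default.

## Segmentation and fractional areas

A pixel belongs to a cover class iff it passes all three inclusive interval
tests of the class rule.  Defaults: %C (living cover) hue 27–90, %Y (yellow
senescent) hue 16–26, %G (healthy green) hue 30–60, all with saturation
60–255 and value 1–255.  Two deliberate readings of ambiguous conventions:

- value 0 (pure black) is excluded even though "all brightness values" is
  the loose description — the operational threshold table is 1–255;
- the saturation cut is 60/255 ≈ 23.5 %, with "24 %" treated as its rounded
  description.

The denominator of every fraction is the ROI disk area πr² (r from
physical diameter × resolution, default 16 cm at 11 px/mm, centred on the
frame unless overridden); the numerator counts the whole frame.  Fractions
above 100 % are therefore legal and meaningful (overhanging leaves).  The
ROI placement is a user decision: a physical-parameter default and an
explicit pixel-space override are both exposed, since the original framing
procedure of any given study is rarely published.

## Indices

All indices average per-pixel values over the %C mask.  DGCI uses hue in
degrees ((H°−60)/60 + (1−S) + (1−V))/3; HSVi uses (H − S/V)/40 − 0.3 with H
on the 0–179 scale and S, V on 0–255 (S/V is a pure ratio).  The HSVi
channel scaling is not self-evident from its formula alone; this convention
maps vegetation hues 27–90 into roughly 0.37–1.95 and is recorded in every
MetricRecord (`hsv_convention`) so alternates can be compared.  Both DGCI
and HSVi consume the quantised HSV raster — the same data the segmentation
saw.

ExG, CIVE and VEG are evaluated on chromatic coordinates.  This matters for
CIVE: on raw 0–255 channels its constant 18.78745 is dwarfed and COMB2
lands near −100, whereas on chromatic coordinates COMB2 sits near its
published working range (≈ −4…17 across corrections).  VEG uses
g/(r^0.667 · b^(1−0.667)); r and b are floored at 1/(3·255²) so pure-green
pixels stay finite without materially moving canopy means.

BA is the ratio of the masked means of b\* and a\*, not the mean of
per-pixel ratios: per-pixel a\* crosses zero on mixed canopies and makes
the ratio distribution heavy-tailed.  Canopies with |mean a\*| < 0.05 are
reported undefined (achromatic): neutral gray does not land at a\* = 0
exactly under the standard conversion matrices, so the guard sits at
conversion-noise scale, far below the |a\*| ≈ 5–90 of vegetated canopies.

Undefined metrics propagate as NaN, never 0 — zero is a legal index value.

## Corrections

**Color.** The affine model (default) solves least squares for a 3×3 matrix
plus offset mapping measured patch colors to reference values; the LUT
model interpolates monotone per-channel tables through the patch pairs.
Published reference chart values are user-supplied, never embedded; the
package ships a clearly-labelled *synthetic* 24-patch set for tests and
demos.  Application clips to [0, 255] and rounds.

**Lens distortion.** The model is a center plus radial polynomial
r_d = r_u(k₀ + k₁r_u + … + k_d r_u^d) mapping undistorted to distorted
radius — the backward map, which is exactly what inverse remapping needs.
k₀ is fixed at 1 because line straightness, the fitting criterion, is
invariant to global scale.  Fitting detects dot centers on a grid target
(intensity-weighted centroids, subpixel), groups them into rows and
columns, and minimises the perpendicular deviation of corrected groups from
straight lines over (center, k₁…k_d); internally the coefficients are
scaled by the target's maximum radius for conditioning.  A non-monotone
fitted radius map is rejected.  Perspective/keystone terms are out of
scope (near-perpendicular lightbox geometry); so is vignette correction.

Undistortion resamples bilinearly and fills out-of-source pixels with the
white background; the exact identity model returns the input bit-exactly.
When both corrections run, color precedes lens correction.

## Statistics

- Replicate CV = sd(n−1)/mean; the sign follows the mean, so
  negative-mean metrics (BA) have negative CVs.  Fewer than two defined
  replicates, or a zero mean, leave the CV undefined.
- Pearson correlations use pairwise deletion; model fits use listwise
  deletion within the fit.
- Kruskal–Wallis is tie-corrected with a χ²(k−1) p-value; an all-identical
  sample returns H = 0, p = 1.
- Dunn's test compares each group to a designated control on joint ranks
  with tie correction; Bonferroni (factor k−1) is the only shipped
  adjustment.
- The permutational factorial ANOVA treats mowing height, irrigation and
  date as fully crossed fixed effects.  F and ηp² = SS_e/(SS_e + SS_err)
  come from the OLS decomposition with Type III sums of squares on
  sum-to-zero contrasts (robust to mild unbalance; Type I would be order
  dependent).  Permutation p-values use Freedman–Lane: residuals of each
  effect's reduced model are permuted, added back to the reduced fit, and
  the effect's F recomputed; p = (b + 1)/(n_perm + 1) so p is never 0.  An
  exhaustive mode enumerates all permutations for tiny designs and is the
  oracle for the sampled mode in the tests.  Date is fixed-crossed, not a
  repeated measure — a deliberate simplification recorded here.

## Synthetic generators

Every generator is a pure function of (parameters, seed), bit-reproducible
via numpy's seeded PCG64 generator; every scene and study records its seed.

**Canopy scenes** render hard-edged elliptical blade strokes (no
anti-aliasing, so every pixel has an unambiguous class) on a white
background inside a circular ROI.  Blade size is physical (half-length
4–9 mm, half-width 1–2.5 mm, scaled by px/mm) so the edge-to-area ratio
tracks resolution.  Stroke HSV is sampled uniformly from configurable
integer ranges that default to strictly inside the classification bands
(green hue 29–62 — deliberately a touch wider than the %G band so %G < %C;
yellow 18–24; saturation 80–220; value 80–230), with a ≥2-unit margin so
the small quantisation of HSV→RGB→HSV round trips cannot flip a class.
Yellow strokes cluster around a few patch centers, as senescing shoots do,
rather than interleaving blade-by-blade with green.  Ground truth is
evaluated on the generated integer HSV raster itself, making
generator-vs-segmentation agreement exact by construction on clean frames.
Optional degradations: an affine color cast, forward radial distortion, and
brightness scaling by the LED warm-up model
radiation(t) = 0.00005t² − 0.0309t + 16.494 W·m⁻² (floored at the 8 W·m⁻²
steady state from t = 360 s).

Not emulated: specular reflections, shadows, soil background, leaf texture
and overlap translucency, perspective, sensor noise and JPEG artifacts.
Passing tests therefore demonstrate the correctness of the computational
pipeline and the recoverability of injected distortions — not robustness to
everything a real greenhouse image contains.

**Study tables** place the factorial design (4 mowing heights × 3
irrigation levels × 8 dates, 6 vessels per treatment, 3 image replicates
per sample) behind a simple effect model: the yellow fraction rises with
date and water deficit and falls with close mowing; the green fraction
moves inversely.  Emulated covariates are affine in the fractions with
noise: visual quality (1–9 scale in 0.5 steps), NDVI/NDRE in [−1, 1], band
reflectances, clipping production and water use.  The VQ and NDVI noise
SDs are solved from the configured target correlations (−0.9 and +0.9)
given the realized predictor SD, with the VQ rounding variance (0.25²/12)
included — so the generator hits its correlation targets by construction,
and the tests check that the whole pipeline reproduces them.  The affine
fraction→covariate links are a modelling convenience for testability, not
a claim about turf biology.  Optional stratified subsampling (e.g. to
n = 316) keeps every factorial cell occupied so the ANOVA stays estimable.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen to keep the
statistics meaningful: 64×64 rasters for classifier-oracle checks, a
900×1200 grid/scene frame for correction recovery (20 scenes), 400–1000
simulated null studies at 1000 permutations for type-I calibration, and
100 seeds × n = 316 for correlation recovery.  Tie-breaks and guards:
round-half-up quantisation; hue wrap at 180; VEG channel floor 1/(3·255²);
BA achromatic guard 0.05; permutation p floored at 1/(n_perm + 1); Newton
inversion of the radius map (25 iterations, safeguarded denominator).

## Known limitations

- The distortion model is radial-only; strong perspective in a grid target
  will be absorbed into (and bias) the radial fit.
- The LUT color model corrects each channel independently and cannot
  represent channel cross-talk; the affine default can.
- Grid-point grouping assumes distortion displaces dots by less than half
  the grid spacing.
- The permutation ANOVA requires every factorial cell occupied; heavily
  missing designs need a different model (e.g. mixed models, out of scope).
- DGCI/HSVi consume quantised HSV; with continuous HSV the values differ in
  the third decimal at canopy-typical chroma.
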