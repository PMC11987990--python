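# Methods

## Problem and scope

The package measures the carapace (dorsal shell) of farmed river crabs
from single top-down images. The full system in production pairs a trained
pose-detection network with the components here; this package deliberately
excludes network training and inference (GPU-scale) and instead provides
everything around it: the loss functions a trainer plugs in, the
evaluation metrics, the annotation formats, the pixel-to-physical
measurement pipeline, and a synthetic scene generator that makes all of it
testable offline with exact ground truth.

## Coordinate conventions

All internal geometry uses the image convention: origin at the top-left,
x rightward, y downward, continuous sub-pixel coordinates. Every quantity
computed (IoU, distances, OKS) is invariant to the choice of frame, so a
single internal frame avoids sign errors; `to_cartesian` supplies the
bottom-left-origin frame some reports prefer, as a display-only transform.
Boxes live in corner form `(x_min, y_min, x_max, y_max)`; the center form
`(cx, cy, w, h)` appears only in the YOLO serialization layer.

Keypoint visibility follows the common pose convention — 0 unlabeled,
1 occluded, 2 visible. OKS and the keypoint losses gate on `v > 0`, so
flags 1 and 2 behave identically; Labelme points carry no occlusion flag
and import as 2.

## Loss stack

**EIoU.** `L_EIoU = L_IoU + L_dis + L_asp` with `L_IoU = 1 − IoU`,
`L_dis = ρ²(b, b_gt)/c²` (squared centroid distance over the squared
diagonal of the smallest rectangle enclosing both boxes), and
`L_asp = (w − w_gt)²/c_w² + (h − h_gt)²/c_h²` (separate width and height
penalties over the enclosing rectangle's width and height). Compared with
aspect-ratio-style penalties, the explicit width/height terms keep a
gradient signal when the ratio is right but the size is wrong. Component
ranges: `L_IoU, L_dis ∈ [0, 1]`, `L_asp ∈ [0, 2]`; the total is zero iff
the boxes coincide.

**OKS keypoint loss.** `L_kpts = 1 − OKS`, where
`OKS = Σₙ exp(−dₙ²/(2 s² kₙ²)) [vₙ>0] / Σₙ [vₙ>0]`,
`dₙ` the pixel error of keypoint `n`, `s = √(box area)` the object scale,
and `kₙ` a per-keypoint tolerance. OKS is an average over labeled
keypoints, so its complement is already in `[0, 1]`; a per-keypoint sum
would not be. The six crab landmarks have no community-standard
tolerances (the COCO sigmas are human-pose-specific), so the default is a
uniform `kₙ = 0.1`, configurable per keypoint through `OKSParams`. At
`k = 0.1` a keypoint error of 8 % of the object scale still scores ≈ 0.7,
which matches the intuition that the shell-margin points are localizable
to a few percent of body size.

**Standard fill-in terms.** The classification, keypoint-confidence and
distribution-focal losses are the standard YOLO-family forms — binary
cross-entropy on the objectness score, binary cross-entropy between each
keypoint's predicted confidence and its visibility indicator (averaged
over the 6 points), and
`DFL = −((⌈t⌉−t)·ln p_⌊t⌋ + (t−⌊t⌋)·ln p_⌈t⌉)` on the discretized box
coordinate. They carry no novelty; they exist so the weighted total
`L = 0.5·L_cls + 7.5·L_EIoU + 1.5·L_DFL + 15·L_kpts + 1.0·L_conf`
is computable end to end with its published weights.

**Numerical choices.** Probabilities are clamped to `[1e-7, 1 − 1e-7]`
before logarithms so boundary inputs give large finite losses rather than
infinities. All losses are pure forward functions — autodiff integration
is the consumer's concern.

## Evaluation metrics

Matching is greedy in descending box confidence: each prediction takes
its best-IoU unmatched ground truth in the same image if that IoU reaches
the threshold. Ties in confidence break by best achievable IoU, then
input order, making the sweep deterministic. Precision and recall are
reported as percentages; a zero denominator raises an error rather than
reporting 0, since an undefined metric silently coerced to 0 corrupts
averages.

AP uses all-points (continuous) interpolation of the precision envelope —
the convention of the YOLO evaluator family — rather than 11-point
sampling. mAP50–95 averages AP over the inclusive grid
0.50:0.05:0.95 (10 thresholds). There is one object class, so mAP = AP.

The keypoint report computes, for every matched instance and every
visible ground-truth keypoint, the Gaussian similarity term
`exp(−d²/(2s²k²))`. Terms below the exclusion threshold (default 0.5) are
dropped and counted; survivors are summarized per keypoint by mean and
sample standard deviation (n−1 denominator, treating the image set as a
sample; a keypoint with a single surviving term reports std 0.0 so the
report stays numeric). The overall mean is the unweighted mean of the
per-keypoint means — the same aggregation that reconciles the published
per-keypoint table with its printed overall value of 91.32 %.

## Measurement pipeline

Width is the Euclidean distance between the left and right shell-margin
keypoints, length between the front and behind points; no max/min
reassignment is performed, so the anatomical labels are authoritative.
Because the four margin points look alike to a detector, a 180° labeling
error is possible; the eyes, which always sit on the anterior half,
disambiguate it. `orientation_check` verifies the eye midpoint falls on
the same side of the left–right axis as the front point and otherwise
rotates the labels 180° (front↔behind and left↔right together). The
operation is idempotent, and an eye midpoint exactly on the axis is
reported as ambiguous rather than silently resolved.

The plate scale divides the known physical side length by the mean of the
four pixel side lengths of the plate quadrilateral, absorbing mild
perspective skew; corners must form a convex, non-self-intersecting quad
(checked with shapely). The default plate is 250 mm a side — the plate
must contain an adult crab, which rules out a centimetre-scale tag — and
the side length is a parameter throughout.

The linear calibration `d_real = a·d_pixel + b` is fitted by ordinary
least squares (scipy). Its purpose is the crab's thickness: the shell
sits above the plate, so its projection is systematically larger than its
caliper-measured size, and the regression absorbs that offset without any
3-D modeling. A fitted regression (n ≥ 2) takes precedence over the pure
plate scale; which path produced a number is recorded in the output's
`calibration_mode`. Width and length may be calibrated by separate models
(the default in the measurement CLI-level pipeline) or share one. Error
reporting uses signed relative error in percent, `(est − truth)/truth ×
100`, summarized by the max and mean of the absolute values — relative
error because it is unit-free and comparable across growth stages.

## Synthetic scenes

The generator emulates the acquisition geometry — a fixed overhead camera,
an orange 250 mm plate on a dark background — not crab photorealism. The
crab body is an ellipse with semi-axes width/2 and length/2 at a uniform
random center and orientation on the plate; keypoints are placed
analytically (side points at the ends of the width axis, front/behind at
the ends of the length axis, eyes at ±30 % of the half-width, 85 % of the
half-length forward), so segment lengths, scale conversion and
orientation all have closed-form ground truth. The bounding box is the
axis-aligned hull of the ellipse plus a 15 % margin standing in for the
chelae, which carry no keypoints.

Defaults: raster 750 × 1000 (a quarter of the 3000 × 4000 capture
resolution, for test speed), plate side 2⁄3 of the short image side
(500 px at the default raster, i.e. 0.5 mm/px), carapace width uniform in
50–80 mm with length 0.85–0.95 of width — the adult size range of the
market-grade animals the rig photographs. `thickness_offset_mm` (default
0) is added to the projected size to form the recorded caliper truth:
with 0 the pure plate scale closes exactly, which is what the end-to-end
closure tests assert; a nonzero offset gives the calibration regression a
real signal, which is how the regression-beats-pure-scale comparisons are
constructed.

Prediction noise is isotropic Gaussian keypoint displacement, uniform box
corner jitter, uniform confidence sampling and Bernoulli visibility
dropout, all under one seed. For Gaussian displacement the OKS kernel has
the closed-form expectation `E[exp(−d²/(2s²k²))] = 1/(1 + σ²/(s²k²))`,
which the noise tests check by Monte Carlo.

Augmentations mirror the training-time set: scale resizing (raster and
coordinates together), horizontal flip — which must swap the left/right
eye and side labels, or flipped data silently teaches a mirrored anatomy;
the flip tests exist for exactly that bug — and a bounded HSV color
jitter that leaves annotations untouched. The default pipeline (original
plus one variant per op) expands a dataset fourfold.

What the synthetic scenes do **not** model: perspective distortion and
camera intrinsics, occlusion and touching animals, water-surface optics,
non-elliptical shell outlines, and detector-specific error structure
(noise here is isotropic and independent across keypoints). Passing tests
therefore validate the arithmetic and the pipeline's contracts, not
real-image detection accuracy.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: oracle
comparisons use 1000 random box pairs (IoU), every correctness pattern of
up to ten ranked predictions (AP), 200–300 random keypoint sets (OKS);
Monte-Carlo checks use 5000 draws; the dataset bookkeeping run generates
1256 small-raster scenes and expands them to 5024; the measurement cohort
is 40 crabs calibrated against a 200-sample fitting set. Scene rasters in
heavy loops are reduced (e.g. 160 × 214) since the geometry, not the
pixel count, carries the information.

## Known limitations

- The pure-scale path assumes the crab lies in the plate plane; out-of-
  plane height appears as a bias that only the fitted regression corrects.
- The plate quadrilateral is supplied by annotation or config; automatic
  plate detection is out of scope.
- Greedy confidence-ordered matching is the evaluation convention, not
  globally optimal assignment; with heavily overlapping detections the
  two can differ.
- Uniform `kₙ = 0.1` is a modeling default, not an estimate from repeated
  human labeling; OKS magnitudes shift with `kₙ`, though rankings are
  stable.
- A single surviving OKS term yields std 0.0 by convention, which
  understates uncertainty for that keypoint.
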