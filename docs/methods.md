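# Methods

This note documents the models, parameter choices and numerical
decisions behind echonode, and what the phantom-based tests do and do
not demonstrate about clinical data.

## Problem setting

Metastatic involvement changes a lymph node in three ways that are
visible on ultrasound: it becomes rounder and thicker (B-mode
morphology), its vascular tree is remodeled from central/hilar to sparse
or peripheral (color Doppler), and it stiffens (strain elastography).
echonode quantifies all three given a frame, a node contour or mask, and
a per-frame pixel-to-millimetre calibration. Detection/segmentation of
the node is deliberately external: the package consumes masks from any
provider (PNG rasters, COCO-style polygon JSON, or its own phantom
generator) through one conversion layer.

Conventions used throughout: 0-based pixel coordinates with x = column,
y = row, origin top-left; contours are implicitly closed polygons with
at least 3 non-duplicate vertices; polygon fill is even-odd and
boundary-inclusive (a pixel center exactly on an edge is foreground),
matching the semantics of an annotator tracing the node capsule. When a
mask has several foreground components, the largest 8-connected one is
kept with a warning — the analysis is per-node.

## Shape morphology

Axes are the side lengths of the minimum-area rotated rectangle
enclosing the contour (exact rotating-calipers solution via the
computational-geometry library, not the fitted ellipse's axes, which are
smaller on irregular outlines). Millimetre values divide by the
calibration. The Solbiati index L/S is classified with the standard
cut-offs (≥ 2 benign-leaning, ≤ 1.5 malignant-leaning, otherwise
indeterminate) and thickness uses the **short** diameter against the
10 mm metastasis marker. One published description multiplies the *long*
axis by the calibration to obtain "thickness"; the clinical definition
of node thickness is the short diameter, so the short axis is used here
and both axes are reported in mm so no information is lost.

Shape variability compares the contour with its own direct least-squares
fitted ellipse (Halir–Flusser style fit; 5-point minimum). Both shapes
are reduced to the seven Hu moment invariants and compared with the
reciprocal-log distance Σ|1/mᵢ(A) − 1/mᵢ(B)|, mᵢ = sign(hᵢ)·log₁₀|hᵢ|.
Two numerical choices matter:

* Moments are computed **analytically from the polygon** (Green's
  theorem, exact closed forms up to order 3) rather than from a
  rasterization, so the score is resolution-independent and invariant to
  translation/rotation/uniform scale to near machine precision (tested
  drift ≤ 1e-2, observed ≪ 1e-3).
* Invariants below 1e-12 in magnitude are treated as exactly zero and
  their terms skipped. Genuine invariants of visibly asymmetric shapes
  are ≥ 1e-7; symmetric shapes (ellipses, k-fold stars) produce pure
  floating-point noise around 1e-30, and feeding noise into 1/log₁₀
  makes the distance meaninglessly jittery.

The ellipse is sampled as a 360-point polygon for the comparison — dense
enough that discretization error is far below the 1e-2 test tolerance.
No malignancy cut-off is applied to the score; it is reported raw.

## Contour sharpness

Every 12th pixel of the rasterized boundary carries a probe: the local
tangent is taken from the two neighboring boundary pixels, and pixels
within ±10 px along the perpendicular and ±1 px laterally are sampled.
Inner/outer membership is decided by the filled mask, not by probe
direction, which keeps the split correct at high-curvature points. The
per-probe score is |mean outer − mean inner| / 255 (absolute value, so
hypo- and hyper-echoic nodes score identically), and the metric is the
mean over probes; probes leaving the frame or with an empty band are
skipped and counted. Defaults (step 12, half-length 10 px, half-width
1 px) span typical capsule widths at 760×574–1552×873 export
resolutions and are configurable. The tangent is handled parametrically,
so vertical tangents need no special casing. No malignancy threshold is
defined for this metric.

## Doppler vascularity

A pixel carries flow signal iff its byte HSV lies in [0,1,1]–
[180,255,255] — i.e. any nonzero saturation and value; color identity is
irrelevant, which makes the metric invariant to the scanner's velocity
palette. Percentage is colored/mask × 100 with the strict < 25 %
malignancy flag. Position is the mean Euclidean distance of colored
in-mask pixels to the mask's area centroid, normalized by the mean
distance of the rasterized contour pixels, with the strict > 0.5 flag;
colored pixels outside the mask are other vessels and are excluded. The
area centroid (not the vertex mean) is robust to uneven vertex spacing.
For a uniformly vascularized disk the expected value is (2R/3)/R = 2/3,
which the implementation reproduces to < 0.01; values slightly above 1
are possible for concave outlines. With zero colored pixels the position
is undefined and omitted from the report.

## Elastography duplex pipeline

The elastogram panel is located and quantified in four steps:

1. **Color-scale removal** — a tall (aspect ≥ 4), narrow (≤ 5 % frame
   width), saturated strip within 10 % of a vertical frame edge is
   blanked. Scanners burn such legends next to the elastogram and they
   can flip the side vote. Best-effort and disable-able; no-op when
   nothing matches.
2. **Ultrasound-region detection** — Gaussian smoothing (σ = 1), gray
   morphological opening (disk r = 2), Otsu binarization, largest
   8-connected component's bounding box. Otsu is used because the
   margin/content split is strongly bimodal; detection fails loudly when
   the component covers < 10 % of the frame.
3. **Colored-side detection** — count pixels with saturation and value
   ≥ 10 left and right of the frame midline; more colored wins; ties and
   all-gray frames raise.
4. **Contour translation** — x shifted by half the region width *toward*
   the colored side (equal-width side-by-side panels assumed; stacked
   layouts are rejected). A `paper_literal_translation` config flag
   reproduces the opposite sign convention found in some pipeline
   descriptions (add when colored side is left); the physically coherent
   direction is the default. The shift is pure addition, so on pixel-grid
   (dyadic) coordinates translating there and back is bit-exact.

Quantification counts the three hue classes (red 0–39 ∪ 136–180, green
40–79, blue 80–135, saturation/value ≥ 1) inside the translated mask.
Percentages are over **all** mask pixels — uncolored pixels dilute every
class, and red + green + blue + uncolored = 100 exactly. The hard
fraction is green + blue under the default blue = hard map (a red = hard
inverse map is configurable for other vendors) with the strict > 40 %
stiffness flag; applying the threshold to all mask pixels (not only
colored ones) matches the vascularity-percentage denominator convention.

## Evaluation metrics

Confusion-count metrics follow the standard definitions and can be
applied at pixel level (one mask pair) or instance level. IoU and Dice
are both reported; the identity dice = 2·iou/(1+iou) is exact and
test-enforced at 1e-12. Mask AP follows the COCO convention: confidence-
descending greedy matching (each reference matched at most once per IoU
threshold), 101-point interpolated precision–recall area, averaged over
IoU 0.50:0.05:0.95, reported on the 0–100 scale. Under this convention
a single perfect detection among two references scores 51/101 ≈ 50.5,
not 50 — a known property of the interpolation grid. Size buckets use
the standard < 32², 32²–96², > 96² px cut-offs.

## Phantom generator

The generator replaces the clinical dataset and defines the test
conditions:

* **B-mode**: smooth background (intensity 245) with a darker node
  (intensity 5), boundary Gaussian-blurred by `blur_sigma`, then 5 %
  multiplicative Gaussian speckle. The high contrast models a strongly
  hypoechoic node and makes the zero-blur boundary a near-maximal
  intensity step (sharpness ≥ 0.9), anchoring the sharpness scale.
  Default node: 110 × 70 px half-axes in a 760 × 574 frame (the smallest
  common scanner export size, kept for test speed).
* **Doppler**: the gray B-mode base as RGB (saturation exactly 0) plus
  exactly round(f·area) painted saturated pixels — the pixels nearest a
  target placed `blob_offset` of the way from centroid to boundary along
  a seed-chosen direction. Exact pixel budgeting is what makes the
  ±0.5-point recovery oracles tight.
* **Elastography duplex**: equal-width panels inside a dark margin, the
  node present in both; the elastogram node area is partitioned into
  exact red/green/blue budgets (class-center hues 0/60/120) alpha-
  blended (α = 0.6) over the gray base. Blending with gray preserves hue
  exactly, so class membership is unambiguous. Optional 12 × 200 px
  rainbow scale bar at the frame edge for adversarial side-detection
  tests.

All generators are byte-deterministic in their seed. What the phantoms
do **not** model: acoustic shadowing and enhancement, realistic speckle
correlation, vendor color maps with continuous palettes, compression
artifacts, neighboring anatomy, or detector segmentation error. Passing
the phantom suites therefore demonstrates correctness of the measurement
logic under known ground truth — not clinical performance.

## Dataset bookkeeping

`plan_split` uses the floor rule: n_train = ⌊0.6·n⌋, n_val = ⌊0.2·n⌋,
remainder to test, with k = 5 augmentation variants per training image
(brightness gain |m| ≤ 0.25, gamma-style exposure |m| ≤ 0.10, Gaussian
blur σ ≤ 2 px; all photometric, so masks are unchanged). This is the
only integer rule consistent with the published counts (397 → 238 →
1190 extra → 1428; 305 → 1098; 92 → 330). The accompanying prose total
of "1429" for the 397-image set is treated as a typo for 1428, and the
published identical validation/test counts (477/477 from 159 remaining
originals) correspond to no integer split of the originals, so they are
not reproduced or asserted. Membership assignment is a seeded
permutation.

## Problem sizes and runtime

The test suite and acceptance script run everything at the 760 × 574
default frame: 20 Doppler phantoms for recovery, 5 blob offsets for
position monotonicity, 8 duplex cases (2 hard fractions × 2 sides × 2
scale-bar settings), 5 blur levels for sharpness, 100 random convex
polygons against the exhaustive rectangle oracle, and 30 random mask
pairs for the metric identities. The full suite completes in about a
minute on one CPU; the acceptance script in about 25 seconds.

## Known limitations

* The sharpness scale depends on the probe geometry; values are
  comparable only under a fixed config (the config snapshot is embedded
  in every report for this reason).
* Colored-side detection assumes the elastogram occupies one half;
  frames cropped to the elastogram alone will be classified as Doppler
  by the autodetector.
* `remove_color_scale` is a heuristic; a node overlay touching the frame
  edge in a tall narrow shape could be blanked (disable via config).
* Pixel-level accuracy on a single mask pair is dominated by the
  background (TN) count and should not be compared across frame sizes.
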