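# Methods

This note documents the models, procedures and numerical choices behind
`herbleaf`, and what the synthetic benchmark does and does not demonstrate.

## Pipeline model and assumptions

The pipeline assumes a digitized herbarium sheet: a light, roughly uniform
paper background; plant material darker and greener than the paper; and
non-plant objects (labels, barcodes, color charts, rulers) that are either
achromatic or saturated in non-green hues. Two structural assumptions do the
heavy lifting:

* **Resolution asymmetry.** Segmenters typically run at a reduced working
  resolution (default 512×512) while the sheet itself is high-resolution.
  Only the mask is ever resized; the sheet image is not, so trait
  measurements keep full pixel fidelity.
* **Bright-gap recovery.** Closely placed leaves that merge into one blob at
  segmentation resolution are separated by masking the *original* image with
  the cleaned, slightly dilated mask (outside → white) and re-thresholding
  at full resolution: the paper gap between the leaves re-emerges as the
  bright class. This is the purpose of the two-pass Otsu in
  `postprocess_mask`.

### Post-processing step order

The clean-mask chain is: resize → binarize → fill holes → dilate (5×5) →
mask the image → binarize the masked grayscale image → fill holes. Filling
before dilating (rather than the reverse) is deliberate: dilation first
would shrink interior holes before the fill sees them, and the fill's
purpose is to stop interior holes from surviving into the masking step.

### Numerical choices

* **Binarization.** Otsu's between-class-variance threshold; the `invert`
  flag selects the darker class (leaves on white). A constant image has no
  threshold and maps to all-background. Step 2 additionally applies an
  absolute score floor (default 0.5): Otsu always finds a *relative* split,
  so on a sheet with no leaf-like pixels it would promote background noise
  to foreground; a pixel whose calibrated score says "closer to background
  than to leaf" is never foreground. Step 6 runs on the luma conversion of
  the masked RGB image, since Otsu is a single-channel method.
* **Resizing.** Binary masks are resized nearest-neighbour (no invented
  sub-pixel structure); fractional score maps bilinearly, thresholded
  afterwards. Silhouettes are resized bilinearly and re-thresholded at 0.5.
* **Connectivity.** Foreground components use 8-connectivity (thin petioles
  survive diagonal steps); hole filling uses 4-connected background. The
  dual choice avoids the standard topological paradox.
* **Dilation.** "Dilate by d pixels" is read as one pass of a
  (2d+1)×(2d+1) square element; an iterative mode (d passes of 3×3,
  identical reach for square elements) is exposed as a config switch.
  Square dilation is implemented with a separable maximum filter.
* **Area gate.** Components are kept iff area > 1000 px, strictly: a
  component of exactly 1000 px is discarded. The gate applies to the
  pre-dilation area; the 10-px candidate dilation exists only to shield the
  masking step, and the crop box is the tight box of the un-dilated
  component.

## Trait measurement

Twenty traits per leaf, pixel units, all but `area` measured on the
hole-filled component (interior damage is not part of the blade outline;
`filled_area − area` quantifies it). The first eleven follow standard
region-property definitions; `diameter` is the maximum Feret diameter
(distinct from `equivalent_diameter = sqrt(4·filled_area/π)`); the eight
ratios follow leaf-morphometry convention with physiological length ≈ major
ellipse axis and width ≈ minor axis:

aspect_ratio = major/minor, rectangularity = filled_area/(major·minor),
compactness = perimeter²/filled_area, circularity = 4π·filled_area/perimeter²,
narrow_factor = diameter/major, per_dia_ratio = perimeter/diameter,
per_length_ratio = perimeter/major, per_length_width_ratio =
perimeter/(major+minor).

The perimeter uses the Crofton estimator (4 directions), which is close to
unbiased on smooth outlines — a rasterized disk of radius 100 gives
circularity within 0.5% of 1 — whereas pixel-edge counting overestimates
smooth contours by up to ~8% and would bias every perimeter-derived ratio.
The trade-off is a known underestimate on long axis-aligned straight edges
(~5% on a rectangle); leaf outlines are smooth, and predicted and
ground-truth traits use the same estimator, so comparisons are unaffected.
No mm calibration is attempted; traits are pixel-valued.

Degenerate inputs: an empty or multi-component mask raises; a 1-px-thin
shape can have a zero minor axis, in which case ratios over it are `inf`
rather than an error.

## Synthetic sheets

`SheetSpec` defaults: 1536×2048 canvas; 3 intact leaves, 1 overlapping
pair, 1 damaged leaf, 2 stems; 25-px minimum gap between distinct specimen
items; color chart, barcode and label distractors in reserved margin bands.
Blades are superellipses (exponent 1.6–3.0) with ≤2.5% smooth margin
wobble, length 260–420 px, aspect ratio 1.5–4, arbitrary rotation. Leaf
color varies mostly in lightness (×0.85–1.15) with small per-channel
jitter, the way dried specimens vary; stems are brown; distractor colors
avoid green. Damage is 2–3 disk bites centered on the margin with radius
0.10–0.18·√area — deep enough to destroy the local margin (such a leaf is
*not* an extraction target), constrained to keep the blade connected and
above half its area. Everything derives from the single spec seed;
identical specs render bit-identically, and each inventory trait vector is
computed from that leaf's raster by `compute_traits` itself (closure by
construction).

What the generator does *not* emulate: venation and texture, real taxon
outlines (lobed, compound, serrated leaves), lighting gradients, mounting
tape, handwriting overlapping the specimen, and color-chart greens. Passing
the synthetic benchmark therefore shows the pipeline's logic is correct
under its stated assumptions, not that a color-model segmenter suffices for
real collections — for those, a trained segmenter's mask is loaded via the
`file` backend, and the classifier is retrained on real silhouettes.

## Reference chroma segmenter

A deterministic stand-in for a trained segmentation model, used on synthetic
fixtures: pixels are scored `exp(−(d/σ)²)` where `d` is the distance to the
leaf reference color in green-opponent coordinates `(G−R, G−B)` and σ = 45.
The opponent space is the point: a plain RGB distance confuses mid-gray with
green at equal Euclidean distance (label text, barcode edges), while
achromatic pixels have near-zero opponent coordinates regardless of
lightness. Working resolution 512×512, bilinear, deterministic.

## Intact-leaf classifier

Default backbone: 19 rotation/flip/shift-invariant descriptors of the
filled silhouette — solidity, extent, eccentricity, circularity, aspect
ratio, narrow factor, three perimeter ratios, rectangularity, the count and
maximum relative area of convexity-deficiency pockets, and the seven Hu
moment invariants (signed log) — standardized and fed to logistic
regression. The discrimination is geometric: overlap unions and bitten
margins open large hull-deficiency pockets; stem-attached blobs and bare
stem slivers are extreme in aspect/narrow-factor; partial blades lose their
symmetry (odd Hu moments). Because the descriptors are already invariant to
the augmentation family (flips, rotations, shifts), augmentation is a no-op
for this backbone and is skipped; the alternative `mlp` backbone (one
128-unit hidden layer over 48×48 silhouette pixels, batch 32) does train
with augmented copies. Training splits 70/30 stratified, seeded; held-out
accuracy, precision, recall and confusion counts are stored on the model.
Ties at the decision threshold (default 0.5) are kept: for trait harvesting,
a spurious crop is cheaper than a silently dropped leaf.

Training data defaults to 881 positives / 1015 negatives, negatives cycling
overlap-union / partial-blade / stem cases. On this synthetic set the
default backbone reaches ~98% held-out accuracy; on real silhouettes (which
include lobed and serrated taxa) a lower figure should be expected.

## Evaluation protocol

Manual inspection does not define a reproducible matching criterion, so
candidates are matched to ground-truth intact leaves greedily by descending
mask IoU with a 0.5 acceptance threshold, one-to-one. FN is a matched
candidate the classifier rejected; undetected is an intact leaf with no
matching candidate; under this reading the reference extraction-count
tables shipped with the acceptance script satisfy
expected = TP+FN+undetected and extracted = TP+FN, and both identities hold
structurally for `ExtractionCounts`. MIoU skips
classes with an empty union rather than scoring them 0 (configurable);
all-zero count sets raise an undefined-metric error rather than silently
returning 0.

## Problem sizes

The test suite and the acceptance script use 20 seeded sheets at 1536×2048
for the end-to-end benchmark, 20 two-leaf fixtures for the merged-mask
separation property, the 881/1015 silhouette set for classifier training,
and 100 random 20×20 / 8×8 rasters for the labelling and metric oracles.

## Known limitations

* The chroma segmenter is a fixture-scale stand-in; it has no notion of
  texture and will fail on green-ish distractors or faded brown specimens.
* The shape classifier is trained on superellipse-derived silhouettes;
  strongly lobed or compound real leaves fall outside its positive class
  and require retraining on real data.
* Overlapping leaves are counted, not resolved: an overlap union is a
  single (rejected) candidate, never split into its member leaves.
* Trait ground truth for overlapping leaves uses the full (amodal) blade
  raster, including occluded pixels.
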