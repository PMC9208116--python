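# Methods

## Scope and model

`segmetrics` evaluates semantic segmentation: every pixel (or voxel) of an
image carries exactly one integer class label, 0 being background by
convention, and a prediction is scored against a reference annotation of
identical shape. Scoring is per sample; dataset-level results are
distributions of per-sample scores, never a single pooled number presented
alone. Instance-level (lesion-wise) detection, soft/probabilistic Dice and
physical-volume overlap are out of scope; a per-pixel probability map is
supported only for ROC/AUC.

## Confusion-matrix metrics

All confusion metrics are evaluated from the exact integer counts
TP, TN, FP, FN of the binary (one-vs-rest) pixel classification, converted
to floating point only in the final division. This makes the scores equal,
bit for bit, to a brute-force per-pixel recount — a property the test suite
asserts on 200 random mask pairs.

Cohen's κ uses the standard marginal-product chance agreement
p_e = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / n²; no bias or prevalence
correction is applied. The products stay below 2⁵³ for any raster that fits
in memory, so p_e is computed exactly. AUC for a hard mask is the area of
the two-segment ROC through (FPR, TPR), i.e. (Sens+Spec)/2; a genuine ROC
sweep requires an explicit probability map and threshold list
(`roc_curve`), with (0,0) and (1,1) appended and trapezoidal integration.

### Edge policies

Zero-denominator cases are not given a value by fiat. The `EdgePolicy`
default is:

* `zero_denominator = None` (undefined): sensitivity on an empty ground
  truth, specificity on an all-foreground one, κ at chance agreement 1.
  Undefined scores are serialized as `NA`, excluded from every mean,
  quantile and histogram, and counted (`n_undefined`, macro exclusion
  counts). Substituting 1.0 here would systematically inflate aggregate
  scores on imbalanced datasets, where empty-truth samples are common.
* `both_empty_overlap = 1.0`: DSC/IoU of two empty masks. Two empty masks
  agree perfectly, and penalizing a correct "nothing to segment" answer
  would be the opposite bias. Users who prefer the stricter convention can
  set this to 0.0 or `None`.

## Average Hausdorff distance

AHD is the arithmetic mean of the two directed average nearest-point
distances (the common definition in the segmentation literature; the
max-of-directed variant is available as `variant="max"`). Distances are
Euclidean on pixel-center coordinates scaled by a per-axis `spacing`, so
anisotropic voxels are handled and AHD scales exactly linearly with
spacing. Nearest neighbours come from `scipy.spatial.cKDTree`; the test
suite checks agreement with a brute-force all-pairs computation to 1e-9.

Point sets default to *all* foreground pixels, which keeps AHD defined for
filled ROIs without contour extraction; `border-only` mode (foreground
pixels with a background face-neighbour or on the image edge) gives the
contour-sensitive variant. Whether the filled or contour convention is used
must be stated when reporting — the two differ on thick structures.

Degenerate cases: two empty masks give 0 (perfect agreement); exactly one
empty mask has no finite distance and defaults to undefined (counted, not
imputed), because a finite stand-in silently distorts distribution
summaries. A `max-diagonal` policy (image diagonal length) is available
when a finite penalty is explicitly wanted. Large finite values are instead
handled at reporting time by clipping (below).

## Multi-class evaluation

Every multi-class metric is defined by one-vs-rest reduction: class c is
scored on the binary masks `truth == c` vs `pred == c`. Aggregation:

* **macro**: unweighted mean of per-class scores. Background inclusion is a
  flag; it defaults to *included* for comparability with common practice,
  but a `GuidelineWarning` fires because a well-predicted dominant
  background inflates the mean. Undefined class scores are excluded and
  counted, never imputed.
* **micro**: one-vs-rest counts summed across classes, the formula applied
  once to the pooled counts. Because each pixel is exactly one positive
  trial across the one-vs-rest matrices, micro sensitivity over all classes
  equals overall per-pixel accuracy — an identity the tests verify — while
  micro accuracy does not (TN pools across classes). AHD has no confusion
  counts and therefore no micro form; requesting it is an error.

## Synthetic scenarios

The generator supplies every test input; nothing is downloaded. It emulates
the standard demonstration baselines:

* `no-segmentation` / `full-segmentation`: the empty and all-foreground
  predictions, whose scores have closed forms (an empty prediction on ROI
  fraction r scores accuracy 1−r and DSC 0; the full prediction scores
  DSC 2k/(n+k)).
* `random-segmentation`: i.i.d. Bernoulli(p) pixels. p has no conventional
  default and must be given explicitly. With truth fraction r, the expected
  DSC is ≈ 2rp/(r+p) (ratio of expectations; accurate at the 10⁴-pixel
  grids used in the tests).
* `perturbed`: the truth translated by an integer offset (zero fill) then
  dilated/eroded with the face-connected structuring element. This stands
  in for models of varying quality — perturbation strength maps
  monotonically to DSC degradation — since no trained model is in scope.

Ground truths are rectangles, ellipses, or masks with a target
background:ROI ratio R. For a ratio, the ROI pixel count is the nearer of
floor/ceil of n/(R+1) in achieved-ratio terms (remainder pixels go to
background); ratios whose ideal count rounds below one pixel are rejected.
The ratio ROI is a row-major prefix block — metric arithmetic depends only
on counts, not geometry, and the block is deterministic. Ratios 9:1
(typical 2D medical image) through 373:1 (a 52³ lesion in a 512×512×200
scan) are the imbalance regimes exercised.

What the generator does *not* emulate: anatomical shape, texture and
intensity statistics, inter-rater annotation noise, multiple ROIs per
image. Passing tests therefore demonstrate metric and pipeline correctness,
not expected scores on real clinical data.

The dataset splitter shuffles with a seeded generator and cuts at
round(n·f) for validation and test, the training partition absorbing the
rounding remainder; the default layout is 64/16/20.

All randomness flows through `numpy.random.default_rng(seed)` instances —
one scalar seed per operation, no global state — so every generated object
is bit-identical across runs and platforms with the same numpy.

## Reporting

`run_evaluation` pairs same-named mask files in two directories (mismatches
fail loudly), scores each pair per class, and writes:

* `scores.csv` — raw records, full precision (`%.17g`), undefined as `NA`,
  never clipped;
* `summary.json` — per (metric, class) quantiles (linear interpolation
  between order statistics) and equal-width histograms over the metric's
  natural range ([0,1] overlap metrics, [−1,1] κ, [0, ceiling] AHD), final
  bin right-closed. Bin edges are computed as the exact convex combination
  (lo·(b−i)+hi·i)/b so decimal edge values land deterministically in the
  upper bin. AHD is clipped at the ceiling (default 250 px) for summaries
  only, with the affected percentage reported to one decimal;
* `overlays/` — truth-vs-prediction rasters for a seeded **uniform** random
  sample of pairs. The draw never sees scores, so high scorers cannot be
  cherry-picked; the tests check the selection frequency of a
  far-above-average sample against the binomial expectation over 500 seeds;
* `manifest.json` — full configuration, seed, package and numpy versions,
  overlay palette and opacity. Re-running an identical manifest reproduces
  every output byte-for-byte (asserted in the tests).

The default metric set is `dsc, iou, sens, spec`, DSC first in all outputs.
Accuracy is computed only on request and the summary then carries an
explicit class-imbalance caveat.

## Problem sizes

The test suite and `scripts/acceptance.py` use grids of 10²–100² pixels
(one 512×512×200 volume for the class-ratio arithmetic), 100–200 random
repetitions for statistical checks and 500 seeds for the sampling-bias
check; the whole suite runs in a few seconds on one CPU. These sizes put
standard errors well inside the asserted tolerances (±0.02 for the κ null
mean, 3 SE for the random-DSC closed form).

## Known limitations

* AHD is quadratic-free via k-d trees but still enumerates all foreground
  pixels; for very large dense 3D masks, `border-only` mode is the
  practical choice.
* Distance metrics compare whole foreground point sets; with multiple
  disconnected ROIs per image, per-instance matching is not performed and
  small missed instances can hide behind well-segmented large ones.
* ROC/AUC requires storing a full probability map per sample; no streaming
  implementation is provided.
* Overlay rendering is 2D only; 3D volumes are scored but not visualized.
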