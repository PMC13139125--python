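# Methods

## Pipeline model

`nodulescan` treats nodule phenotyping as four composable stages around an
arbitrary per-patch detector.

**Tiling.** A `W × H` image is covered by a grid of `P × P` patches
(`P = 512`) at stride `P − o` with overlap `o = 64` px. Grid origins run
`0, s, 2s, …` per axis; the final origin is clamped to `dim − P` so the last
patch ends exactly at the image border (images smaller than `P` get a single
zero-padded patch at origin 0). Clamping keeps every patch full-size — what a
fixed-input detector expects — while guaranteeing that the patch union covers
every pixel. The overlap is chosen against the nodule size distribution:
with the largest nodule side (57 px) below the overlap (64 px), **every**
nodule is fully contained, unclipped, in at least one patch; this is proved
property-style in the test suite. Annotations are remapped per patch by
translation and clipping; boxes with empty intersection are dropped.

**Refinement.** Each patch's detections pass an edge filter: a box any of
whose sides lies strictly within `t = 5` px of a patch boundary is removed,
the stricter of the possible readings — such a box is a partial view whose
nodule the overlap guarantees is wholly visible in a neighbor. A boundary
that coincides with the photo's outer border is exempt by default
(`exempt_image_border=True`): a nodule hugging the image edge exists *only*
in a border patch, so filtering it there would lose it irrecoverably; the
flag can be disabled to mirror a uniform-filter reading. Survivors are
translated by the patch origin into image-global coordinates and pooled, and
greedy NMS runs once per image: drop confidences `< 0.2`, sort by confidence
descending (ties by x then y ascending, making output deterministic), keep
the top box, remove remaining boxes with IoU `≥ 0.2` against it, repeat.
Hard suppression is used, not soft reweighting, and IoU `≥` (not `>`) the
threshold suppresses. The low IoU bar is appropriate because real nodules
rarely overlap in 2D projection, so any substantial overlap is a duplicate.

All geometry is continuous (0-based pixel coordinates, top-left origin,
closed intervals, `area = width · height`), avoiding half-open pixel-grid
±1 ambiguities; IoU of a box with itself is exactly 1.

**Traits.** From the final box list: `count`; `height`/`width` as the
spans of box-center y/x; `sdx`/`sdy` as population standard deviations of
center x/y and `sdxy = sdx/sdy`; nine statistics (min, max, SD, mean,
median, p5, p25, p75, p95) over per-box areas and over center-y values.
Percentiles interpolate linearly between closest ranks; SDs divide by N
(`ddof` configurable — population SD matches the default of the mainstream
array stack). Degenerate inputs never raise: zero nodules gives
`count = 0` and 23 NaNs; one nodule gives zero dispersions and NaN `sdxy`
(0/0); `sdy = 0` with `sdx > 0` gives NaN `sdxy` with a logged warning.
The 24-name schema and column order are frozen for byte-stable CSVs.

**Evaluation.** Predictions match ground truth one-to-one, greedily by
descending IoU at threshold 0.5 (configurable) — the de-facto
detection-evaluation convention; the threshold-matching structure of
realistic scenes (spatially separated nodules) makes greedy equal to optimal
assignment, verified against a brute-force maximum-matching oracle in tests.
Zero-denominator conventions: an image empty on both sides scores
P = R = F1 = 1; an undefined P or R with the other side non-empty resolves
to 0. Images stratify by true count into bins ≤5, 6–10, 11–20, 21–30, ≥31
(count 31 belongs to the top bin so the bins partition ℕ); the overall row
is the unweighted mean of per-bin means — each density regime counts
equally, regardless of how many images landed in it.

**Phenotype statistics.** Z-score outlier removal is cell-wise (value →
missing, never whole-accession) and single-pass: Z uses the unfiltered
mean/SD, and a zero-SD trait never loses values. Correlations are
pairwise-complete Pearson (≥ 3 complete pairs per cell; zero-variance
traits give missing cells). Downstream GWAS (rMVP/FarmCPU, kinship, PCA) is
out of scope; the export is the `Taxa` + 24-trait CSV those tools read.

## Synthetic scenes and the mock detector

The generator emulates blue-blotter imaging: flat blue background, a dark
sinuous vertical taproot stripe, nodules as filled tan ellipses with exact
tight bounding boxes. The larger box side is lognormal with
`σ = 0.45` and `μ = ln(19.93) − σ²/2` (untruncated mean equal to the
measured 19.93-px mean nodule length), truncated to [6, 57] px so the hard
maximum matches the measured 57-px maximum; the minor side is 0.65–1.0 of
the major. Placement enforces a minimum box-to-box gap (default 10 px), so
ground-truth pairs have IoU exactly 0, and optionally clusters centers near
the taproot curve. An optional QR-like label stamp provides a negative
control for intensity detectors. Everything is reproducible from the seed.

What the generator does **not** model: occlusion and touching nodule
clusters, lighting gradients and shadows, lateral-root texture that can
mimic nodule color, soil debris, and the calibrated spatial statistics of
real accessions. Tests passing on these scenes therefore certify the
*plumbing* — coordinate bookkeeping, duplicate collapse, trait algebra,
protocol arithmetic — not detector robustness on field images.

The mock detector corrupts ground truth with independent per-box misses
(probability `fn_rate`), Gaussian corner jitter (`jitter_sd`), uniform
confidences on a configurable interval, and Poisson-count spurious boxes
placed disjoint from all truth. Per-patch RNG streams are derived from the
base seed and the patch name (CRC32), so results are independent of patch
processing order.

## Numerical and design choices

- Edge filtering happens in the patch-local frame, where "patch edge" is
  well defined; the NMS confidence floor applies inside NMS only, not as a
  detector inference floor.
- Detections CSVs sort rows by (y, x, −confidence) and are re-read with
  round-trip float parsing, so write → read → write is byte-stable.
- The blob backend thresholds the red-minus-blue channel difference
  (> 30 by default) and filters connected components to 12–6000 px²;
  confidence is the component's fill fraction of its bounding box (an
  ellipse fills ~π/4 ≈ 0.79). It is a genuine classical detector for
  pixel-level runs, with no pretension to trained-model accuracy.
- Bin-average arithmetic on four-decimal per-bin inputs carries the input
  rounding: the equal-weight mean of published-style per-bin recalls can
  differ from a headline computed on unrounded values by ~1e-4. The tests
  pin the exact arithmetic of the rule.
- Problem sizes in the default test run (scene counts of 25–200 at
  600 × 900 to 2300 × 4600 px, 1–72 nodules) were chosen as the smallest
  sets that make the binomial/Poisson recovery checks statistically sharp
  (3-standard-error bands) while keeping the suite quick to iterate.

## Known limitations

- 2D only: areas are projected box areas; occluded or stacked nodules are
  undercounted by construction.
- The edge filter can, in principle, drop a nodule whose side exceeds
  `overlap − 2t + (P mod stride)` adjustments — concretely, boxes with a
  side in (54, 57] px have a ≤ 3-px-wide set of unlucky positions per
  448-px stride period where every containing patch sees them within 5 px
  of an edge. With lognormal sizes this is a ≲ 10⁻⁵ event per nodule; the
  exact-recovery property in the acceptance suite holds over its 50 scenes.
- Greedy NMS keeps the highest-confidence duplicate, not a fused box; with
  jittered detectors the kept box inherits that detection's jitter.
- The yolo adapter passes through externally trained weights and
  hyperparameters untouched; training, augmentation, and mAP curves are out
  of scope.
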