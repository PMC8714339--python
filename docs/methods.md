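# Methods

## Phantom model

Each phantom is a 2-D reflectivity map rasterized from sampled geometry,
then corrupted by multiplicative speckle. Classes and default mean
reflectivities (dimensionless, in [0, 1]):

| id | class      | contrast | rationale                          |
|----|------------|----------|------------------------------------|
| 0  | background | 0.20     | liver-like mid-dark parenchyma     |
| 1  | wall       | 0.55     | echogenic gallbladder wall         |
| 2  | lumen      | 0.05     | anechoic bile                      |
| 3  | lesion     | 0.70     | moderately echogenic mass (target) |
| 4  | stone      | 0.95     | strongly reflective calculus       |

Geometry: the lumen is an axis-aligned ellipse (semi-axes drawn uniformly
from `lumen_axes_range`, center jittered ≤8 % of the image while keeping the
outer wall inside the frame); the wall is the surrounding elliptical annulus
of sampled thickness; lesions are disks placed uniformly inside the lumen
*shrunk by the lesion radius*, so each disk is contained in the lumen by
construction (degenerate small lumens shrink the radius instead of
rejecting). A stone, drawn with probability `stone_probability`, is the
proximal half-disk near the distal lumen wall; its distal column is darkened
(×0.35) in the image only, and only over background/lumen pixels — the
shadow is cosmetic realism and never alters the label mask or the lesion
photometry. All shapes are rasterized with the strict normalized-distance
rule (pixel centers with elliptical distance < 1), and the mask is derived
from the noiseless geometry, so ground truth is pixel-exact.

Speckle is unit-mean gamma multiplicative noise: image = clean × G,
G ~ Gamma(k, 1/k) i.i.d., clipped to [0, 1]. Var(G) = 1/k; the default
k = 4 gives the strong granularity of B-mode imaging, and k ≈ 15 is used
for the "easy" training tasks. Clipping truncates the upper tail, which is
why moment checks of the noise model use the unclipped form
(`apply_speckle(..., clip=False)`).

Seeding: sample *i* of a dataset uses `derive_seed(master, i)`, a fixed
splitmix64-style hash, so manifests are portable and any sample can be
regenerated in isolation; the speckle stream is derived from the sample seed
the same way. Identical (params, seed) → bit-identical output.

What the phantoms do *not* emulate: acoustic wave propagation, depth-
dependent attenuation and focusing, refraction/reverberation artifacts,
anatomical clutter, probe-dependent point-spread functions, and 3-D
structure. Tests passing on phantoms therefore certify the pipeline's
correctness and learnability on intensity-separable targets — not clinical
performance.

## Network

Encoder stage: 3×3 convolution (stride 1, same padding) → batch-norm → ReLU,
then 2×2 stride-2 max pooling that records the argmax position of every
window. Decoder stage (mirrored): max-unpooling — scatter the coarse map to
the recorded positions, zeros elsewhere — then the same conv block. A final
1×1 convolution maps to per-class scores at input resolution; valid inputs
have spatial sizes divisible by 2^stages.

Defaults: widths (32, 64, 128), i.e. three stages, chosen as a desk-scale
compromise (the classic five-stage VGG-style widths are available through
`encoder_widths`); kernel 3; batch-norm on; He-normal initialization.

Pyramid pooling (bins default (1, 2, 3, 6), the canonical grid set) is
applied to the deepest pooled map. Branch: adaptive average pooling to b×b
(near-equal integer cells, so non-divisible sizes are handled) → learned
1×1 conv to `channels // n_bins` channels → batch-norm → ReLU → bilinear
upsampling to the bottleneck size → concatenation with the input map →
3×3 fusion conv block back to the bottleneck width. Bilinear resizing is
implemented as an exact linear map (precomputed interpolation matrices,
half-pixel centers), so its backward pass is the transpose — decoder
upsampling itself always uses index unpooling, which is the architecture's
defining trait; interpolation appears only inside pyramid branches.

The whole stack is NumPy with hand-written backpropagation: convolution via
im2col (input gradient computed as a same-padded convolution with
spatially flipped, in/out-transposed kernels), standard batch-norm
backward, float32 throughout. Gradient correctness is covered by
central-difference tests, and a smoke property checks that every learnable
parameter receives a nonzero gradient.

## Training and evaluation

Loss: mean per-pixel softmax cross-entropy over the five classes, unweighted
(class weighting is a possible extension; the easy tasks do not need it).
Optimizer: Adam, lr 1e-3, β = (0.9, 0.999). The train/validation split is a
seeded permutation (default 20 % validation, at least one sample each side);
batch order reshuffles per epoch from a stream derived from the training
seed, so runs are bit-reproducible single-threaded. Divergence is detected
both on the loss and on the weights after each epoch (ReLU maps NaN
activations to 0, so a NaN loss alone is not a reliable signal) and raises
an error naming the epoch.

Evaluation is micro-averaged: confusion counts for the target class
(lesion, id 3) are pooled over all pixels of the dataset before IoU,
precision and recall are computed — matching their count-based definitions.
A score whose denominator is zero (no target anywhere, or no detections) is
reported as an explicit `None` sentinel rather than 0. "Accuracy" in the
training history is overall pixel accuracy.

`compare_variants` trains the plain (no pyramid) and pyramid arms with
identical data, seeds and hyperparameters, evaluates each on its held-out
split, and reports per-arm means ± sd over seeds plus per-seed
pyramid-minus-plain deltas. The intensity-threshold baseline (predict
lesion inside a contrast band) provides the learnability yardstick: on
easy phantoms any trained arm should beat it.

Problem sizes used by the test suite and acceptance script — 64×64 images,
encoder widths (16, 32), 80–200 phantoms, ≤30 epochs (200 for the 5-image
memorization check, which uses widths (32, 64): memorization needs spare
capacity) — are desk-scale choices that keep full runs in minutes on one
CPU core while leaving the phantom task comfortably learnable.

## Metrics conventions

IoU, precision and recall are the standard count-based forms given above;
the identity 1/IoU = 1/Pre + 1/Recall − 1 (TP > 0) and the bounds
IoU ≤ min(Pre, Recall) are enforced as property tests. Binary collapse at
the target class makes IoU symmetric under swapping prediction and truth
(TP fixed, FP↔FN exchange).

## Cohort statistics

The bundled cohort: 300 patients examined for suspected gallbladder
malignancy; 32 pathologically confirmed malignant (17 adenocarcinoma, 8
squamous, 5 adenosquamous, 2 villous cystic tumors) and 168 benign (67
polyps, 19 adenomas, 14 biliary sludge, 32 acute and 36 chronic
cholecystitis with stones). Imaging concordance against pathology:
conventional ultrasound 25/32 malignant and 161/168 benign;
contrast-enhanced 28/32 and 166/168.

P16 positive counts per group are not published as integers; they are
reconstructed as `round(rate × n)` and flagged as reconstructed in the
report. The published chronic-cholecystitis rate (81.56 %, n = 36) matches
no integer numerator; the nearest count 29/36 = 80.56 % is used and the
report carries a data-inconsistency note; it is never used as a test value.

Rates are reported to two decimals with half-up rounding (the tables'
convention, 25/32 → 78.13); note the published tables themselves round
17/32 = 53.125 down to 53.12, so printed-value comparisons allow ±0.01
percentage points.

IHC grading bands by fraction f of cells with brown-yellow staining:
negative f < 0.05, weak positive 0.05 ≤ f < 0.30, positive
0.30 ≤ f ≤ 0.60, strong positive f > 0.60. The verbal bands overlap at
their endpoints; the convention here is lower-inclusive except the strong
band ("more than 60 %" read as strict). Weak positive or above counts as
positive expression.

χ² tests are Pearson without continuity correction by default (a flag
enables the Yates-corrected 2×2 form), df = (rows−1)(cols−1); degenerate
tables (zero marginals, fewer than 2×2) raise instead of returning a value.
No multiple-testing correction is applied, matching the source analysis
style.

## Known limitations

* Phantom realism is geometric/photometric only (see above); reported
  pyramid-vs-plain deltas quantify behavior on phantoms, not clinical
  improvement.
* The NumPy network is CPU-bound and desk-scale; no GPU kernels, mixed
  precision, pretrained encoders, or 3-D support.
* Micro-averaged metrics weight large lesions more than small ones;
  per-image (macro) aggregation is not provided.
* P16 analyses inherit the reconstruction uncertainty of the positive
  counts (±0.5 case).
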