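# Methods

`kcc` implements a complete single-stage tree-crown detection pipeline for
UAV orthophoto tiles of planted shelterbelts: dataset tooling in the Pascal
VOC dialect, anchor-prior clustering, offline and online augmentation, a
CoordConv/CBAM-augmented detector with three anchor-based heads, a training
recipe, and the detection metrics used to score it.  This note records the
models, the parameters that matter, and the design choices made where the
method left the design open.

## The detection model

The detector is a YOLO-family single-stage network.  An RGB tile (default
640×640) passes through a convolutional backbone of CBS blocks
(conv → batch-norm → SiLU) and four ELAN aggregation stages separated by
two-branch MP downsampling blocks, emitting feature maps at strides 8, 16
and 32.  The neck applies SPPCSPC (CSP-wrapped spatial pyramid pooling at
kernel sizes 5/9/13) to the deepest map and fuses scales along a PANet
top-down plus bottom-up path.  RepConv blocks (3×3 conv+BN, 1×1 conv+BN and
identity-BN branches, summed) feed a 1×1 convolution per scale that emits,
for each of 3 anchors per cell, `(tx, ty, tw, th, obj, class logits)`.

Predictions decode as

    center = (2·σ(txy) − 0.5 + cell) · stride
    size   = (2·σ(twh))² · anchor
    score  = σ(obj) · max class probability

Class probabilities use a softmax by default: the five crown classes (four
species plus dead trees) are mutually exclusive, and competitive class
scores suppress confident duplicate detections of a second species on the
same crown.  Per-class sigmoids remain available (`cls_activation="sigmoid"`,
`cls_mode="bce"`).

Three enhancements toggle independently from `ModelConfig`, which builds all
eight structural variants (baseline included):

* **Clustered anchors** (`use_kmeans_anchors`) — the 9 (w, h) priors come
  from K-means++ clustering of training-box dimensions rather than the
  hand-set defaults of the upstream baseline.
* **CoordConv** (`use_coordconv`) — the two 1×1 entry convolutions of every
  backbone ELAN see two extra channels holding x/y coordinate ramps
  normalized to [−1, 1] (a degenerate axis maps to 0), giving the layer
  explicit positional awareness.  Both entry convolutions are replaced; the
  flag records this choice.
* **CBAM** (`use_cbam`) — convolutional block attention at exactly five
  sites: the three backbone taps before the neck and the two upsampling
  outputs inside the top-down path; the bottom-up path is left untouched.

### CBAM details

Channel attention pools each channel to its global average and maximum,
passes both descriptors through one shared bottleneck (C → C/r → C, r = 16
by default, mirroring the original module), mixes the paths with trainable
scalars α and β (initialized to 1), and gates with a sigmoid.  The scalars
are scalars, not per-channel vectors, and the bottleneck is shared between
the two pooling paths.  The bottleneck's rectifier is leaky (slope 0.1): at
the width-1 bottlenecks of desk-scale models a hard ReLU goes dead easily,
silencing the max-pooling path and its parameters.

Spatial attention pools the *channel-attended* map across channels (mean and
max per position), sums the two maps into a single channel, applies a 7×7
convolution (padding 3, no bias — a bias would only shift the gate
uniformly) and a sigmoid.  Summation is the default merge; the original
module's two-channel concatenation is selectable (`merge="concat"`), and the
sigmoid can be disabled for literalists who want the ungated convolution
output.

## Anchor clustering

Box dimensions cluster under a configurable distance: `1 − IoU` of
corner-aligned boxes (default; the community convention for anchor fitting)
or plain Euclidean distance on (w, h).  Seeding is either deterministic
farthest-point (after a random first pick, each next centre maximizes the
distance to its nearest centre) or classical D² sampling.  Lloyd iterations
assign to the nearest centre and recenter at the arithmetic per-cluster mean
of (w, h).  The mean is not a strict descent step under the IoU objective,
so the iteration runs to an assignment fixed point while tracking the best
iterate seen; the best centres are returned and the reported objective
history is the running best, monotone by construction.  Input dimensions are
sorted before seeding so results do not depend on file enumeration order.
An emptied cluster is reseeded at the point farthest from all centres.  The
9 anchors sort by area and split 3-per-scale onto strides 8/16/32.

## Datasets and augmentation

Annotations are labelImg-dialect VOC XML: 1-based inclusive on disk,
converted to 0-based half-open internally (so `width = xmax − xmin`) and
converted back exactly on write; read∘write is an identity.  Splitting
supports a ratio mode (largest-remainder rounding) and an explicit-counts
mode; the survey's published 3048/872/436 partition of 4356 tiles matches no
standard rounding of 7:2:1, so it is reproduced through counts.

Offline augmentation materializes, per input image, ten exactly
label-synchronized variants — horizontal and vertical flips, three quarter
turns, a transpose, contrast 0.7 and 1.3, Gaussian noise σ = 0.02 and 0.05 —
for an 11× expansion matching the published 396 → 4356 growth.  Rotations
are restricted to quarter turns because arbitrary angles inflate axis-aligned
boxes; the published transform list is partial ("and other techniques"), so
only the multiplier is anchored.  Mosaic splices four randomly scaled images
around a random interior point, clipping boxes to their quadrant and
dropping any whose clipped area falls below 0.25 of the scaled original.
MixUp blends two images convexly and unions their labels with weights λ and
1 − λ (λ ~ Beta(8, 8); a fixed-λ mode exists for tests); the weights ride
along as per-box loss weights.  Online, a fraction `mosaic_ratio` (default
0.8) of samples per epoch pass through Mosaic and, of those, `mixup_ratio`
(default 0.8) additionally through MixUp with a second, freshly built mosaic
as partner — MixUp is never applied to a non-mosaic sample.

## The synthetic scene generator

The authors' imagery is not deposited, so `kcc.scenes` renders what the
pipeline needs: top-down tiles with a mottled sandy background and five
crown classes drawn as shaded elliptical or irregular-blob masks with
per-class size and RGB distributions — large green elm and silvery-green
oleaster crowns, conical bright poplars, small dark saxaul shrubs, and
small gray-brown dead trees — sampled with the survey's class imbalance
(34.75/13.43/6.55/36.90/8.36 percent) and placed by rejection sampling under
an IoU overlap cap (default 0.3; ~6–13 crowns per 640-px tile, matching the
survey's ≈9 trees per tile).  Generation is bit-deterministic per seed.

The generator emulates geometry and label statistics, not radiometry: no
shadows cast between crowns, no understory vegetation, no sensor noise
model, no georeferencing.  Tests passing on these scenes demonstrate that
the pipeline's machinery — I/O, clustering, augmentation, optimization,
evaluation — is correct and can fit canopy-like imagery; they say nothing
about accuracy on real UAV data.

## Training

The recipe follows the published settings: Adam (β₁ = 0.937 — the stated
"learning rate momentum" — β₂ = 0.999), initial learning rate 0.01, weight
decay 1e-4, cosine annealing to 0, 300 epochs, batch 4, NMS threshold 0.3,
confidence 0.5 (the stated settings also mention 0.3; 0.5 is adopted for
evaluation and 0.3 remains available as an option).  Three additions keep
from-scratch CPU training stable: a 3-epoch linear warmup, global
gradient-norm clipping at 10, and a weak L2 pull (0.01) on the raw box
logits of positive cells.  The last one matters numerically: the `(2σ)²`
size parameterization saturates — once a logit overshoots far enough that
the sigmoid derivative rounds to zero, the box pins at 4× its anchor and
cannot recover — and the quadratic pull is negligible in the working range
but dominant exactly where the task gradient has vanished.

The loss is the conventional single-stage composite (the source method never
publishes its loss): mean (1 − CIoU) over positives, binary cross-entropy on
objectness over every cell (positives carry their MixUp weight), and softmax
cross-entropy on class logits at positives.  Default term weights follow the
upstream convention (box 0.05, obj 1.0, cls 0.5·nc/80); the scaled-down
runs in this repository use box 1.0 / cls 0.5, which balance the terms for
Adam at tiny batch sizes.  A ground-truth box is positive, at every scale
whose anchor passes dimension-IoU > 0.5 (best-anchor fallback otherwise), at
its center cell and — the center-prior convention the (−0.5, 1.5) offset
range exists for — the two adjacent cells nearest its center; center-cell
claims take priority over neighbor claims so one crown never trains over
another's center.  After the last epoch, BatchNorm running statistics are
recomputed as exact train-set averages: at tiny batch sizes the
exponentially averaged statistics (momentum 0.03) lag the weights enough to
distort eval-mode inference.

## Evaluation

A detection is a true positive iff it shares the ground-truth class and
overlaps an unmatched ground-truth box of the same image with IoU above the
threshold (0.5), matched greedily one-to-one in descending score order with
highest-IoU tie-break.  Precision, recall and F1 follow the standard
formulas with 0/0 → 0.  AP is the exact area under the interpolated
(monotone-envelope) precision–recall curve; an 11-point mode exists for
comparison.  mAP averages per-class AP over the classes present in the
ground truth (a class with no boxes has undefined AP, reported as 0 with a
flag but excluded from the mean); mAP@[0.5:0.95] averages additionally over
IoU thresholds 0.50–0.95 in steps of 0.05.  NMS is class-wise greedy at
threshold 0.3.  The evaluator is verified against an independently coded
exhaustive reference on random scenes to 1e-6.

## The `nd` engine

All neural computation runs on `kcc.nd`, a compact reverse-mode automatic
differentiation engine over numpy arrays: a `Tensor` records operations and
back-propagates through broadcast arithmetic, reductions, im2col-based
convolution, max pooling, nearest upsampling, fused batch normalization and
the usual nonlinearities; `Adam` implements the optimizer.  Gradients are
verified against central finite differences operation by operation.  The
default dtype is float64 (finite-difference tests need it); training runs
switch to float32 for speed.  Numerically, the sigmoid derivative is
computed as σ(z)·σ(−z) with the stable branch per sign, which keeps it
nonzero far into saturation.

## Problem sizes used in tests

The test suite and acceptance script run the full pipeline at desk scale:
width_scale 0.125 models (channel widths ⅛ of the base configuration),
64–160-px tiles, and 10-scene datasets expanded 11× offline before a
30-epoch training run — the same pipeline order as the published experiment,
which expands 396 tiles to 4356 before its 300-epoch run.  Scaled-down
scenes keep crowns spanning multiple stride-8 cells (as real crowns do at
640 px) rather than shrinking them proportionally into sub-cell specks.
One full-resolution 640-px forward pass checks the 80²/40²/20² grid
arithmetic.

## Known limitations

* No pretrained weights, EMA, multi-GPU, auxiliary heads or ONNX export.
* The engine is CPU-bound; full-width 640-px training is out of reach — the
  architecture and recipe are faithful, the published accuracy numbers are
  not reproducible without the authors' data and GPU-scale compute.
* Arbitrary-angle rotation, CutMix and HSV jitter are not implemented.
* COCO-protocol evaluation compatibility is not attempted; metrics follow
  the definitions above.
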