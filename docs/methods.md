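# Methods

This note records the model, its assumptions, the parameter defaults
and the numerical choices — the reasoning a maintainer needs, in one
place.

## Problem setting

A stem cross-section micrograph contains four annotated structures:
the stem perimeter ("out", one per image), the central cavity ("in",
one per image), an inner band of large vascular bundles ("big") and a
peripheral ring of small vascular bundles ("small").  The small
bundles are the hard target: at full resolution they are boxes a few
to ~16 pixels wide, densely arranged, blurry-edged and low-contrast.
The task is box-level detection and classification; region metrics
(Dice/IoU) are computed from box unions, not instance masks.

## Dynamic snake convolution

A snake kernel is one-dimensional: k taps spread along either the
horizontal or the vertical image axis, each displaced perpendicular to
that axis by a learnable offset Δy_c.  Tap c of a horizontal kernel
centred at (x_i, y_i) samples (x_i + c, y_i + Δy_c).  Choices made
where the operator definition leaves room:

* **Interpolation**: fractional sample positions are resolved by
  bilinear interpolation with zero padding outside the grid (the
  deformable-convolution convention).
* **Offset sharing**: offsets are per-tap and per-layer, shared across
  channels and spatial positions.  This keeps the sampling pattern a
  rigid per-layer shape (cheap, stable) rather than an input-dependent
  field.
* **Clamp**: |Δy| ≤ 1.0 by default, re-imposed after every optimiser
  step.  Unbounded offsets let early training tear the kernel apart.
* **Axis alternation**: the two convolutions inside a bottleneck use
  horizontal then vertical axes, so the composed receptive field can
  bend in both directions.
* **Learnability**: offsets are ordinary parameters trained end to
  end (they receive gradients through the bilinear weights).

### Quantization and distribution shifts

Kernel weights can be vector-quantized to a signed b-bit integer grid
in blocks of BLK weights (default BLK = 64; the block size is a free
parameter of the scheme).  The per-block linear-mapping scale is
max|w| / (2^{b−1} − 1); the symmetric denominator keeps every rounded
value on the admissible grid [−2^{b−1}, 2^{b−1} − 1] without clamping
distortion, so the mapping error is at most half a step.  Rounding is
half-to-even; an all-zero block uses scale 1.

Dequantization is corrected by two fitted shifts:

* **KDS** (per block): scale ξ is the closed-form least-squares
  minimizer of Σ(w_q·ξ − w)², i.e. ξ = Σw_q·w / Σw_q²; bias ξ_s is the
  mean residual.  Degenerate blocks (Σw_q² = 0) fall back to ξ = 1,
  ξ_s = mean(w).  The fit direction is reconstruction — recover w from
  w_q — which is the only direction that lets the dequantized kernel
  approximate the original tensor.
* **CDS** (per output channel): the same least-squares recipe applied
  once more, per channel, to the KDS-reconstructed tensor.

The quantized path is functional (used at inference/analysis time);
training runs in float32.  No integer arithmetic speedups are
attempted.

## Detector assembly

The backbone is a stride-2 convolution cascade with C2f stages
(split → n bottlenecks, every intermediate concatenated → 1×1
projection) emitting P2/P3/P4/P5 at strides 4/8/16/32.  With the
DSConv flag on, the bottleneck convolutions and the C2f channel-adjust
convolutions are snake instances (the 1×1 adjusters become single-tap
snake kernels, i.e. a learnable sub-pixel shift).  The neck and heads
always use plain kernels; the serpentine operator is a feature
*extraction* device.

The MFF neck continues the top-down path to stride 4 and re-descends:

    F4 = C2f(up(P5) ⊕ P4)      stride 16
    F3 = C2f(up(F4) ⊕ P3)      stride 8
    F2 = C2f(up(F3) ⊕ P2)      stride 4   → head 1
    T2 = C2f(down(F2) ⊕ F3)    stride 8   → head 2
    T4 = C2f(down(T2) ⊕ F4)    stride 16  → head 3
    T5 = C2f(down(T4) ⊕ P5)    stride 32  → head 4

Up(.) is nearest-neighbour 2×; down(.) a stride-2 3×3 convolution; ⊕
is channel concatenation with the deeper/processed map first (an
element-wise-add fusion mode exists behind a switch).  With MFF off
the neck is the standard three-head FPN+PAN at strides 8/16/32.
Channel widths follow presets (tiny 8/16/24/32/32 up to default
32/64/128/256/256); the architecture source gives no widths, so these
are package choices sized for CPU testing and for a full-scale run
respectively.  Activation is SiLU after every convolution +
batch-norm pair.

Heads are anchor-free: each cell predicts four softplus-activated edge
distances scaled by the stride (an unbounded, always-positive decode)
plus per-class logits.  The class bias initializes at −4 so an
untrained model scores every cell near zero.

### Assignment, loss, decoding

A ground-truth box routes to one head by size — level =
clip(⌊log2(max(w,h)/s_min)⌋), so boxes up to ~2× the finest stride
land on the stride-4 grid — and to the cell containing its centre plus
the two nearest neighbour cells (one per axis).  The densified
assignment stabilises training on coarse grids; a box centred outside
the image is skipped with a warning.

Total loss = 5·(box loss mean over positives) + (classification BCE
summed over all cells / positive count).  The box loss is the
corrected-form, corner-penalty PIoU by default (λ = 1.3; the weight
coefficient is not pinned by its source, and 1.3 sits in the range
used in the PIoU literature) or CIoU.  For CIoU the aspect trade-off
α = v/((1−IoU)+v) is treated as a constant in the gradient, the usual
convention, and α := 0 at the IoU = 1, v = 0 corner.

Decoding applies per-class greedy NMS (IoU > 0.45 suppresses), clips
to image bounds, drops degenerate boxes and sorts by confidence.

### The PIoU ambiguities

The loss as printed in its sources has three internal tensions, all
exposed as configuration rather than silently resolved:

1. **Overlap factor**: the literal (1 − IoU − e^{−P²}) is −3/e at
   perfect overlap under λ = 1 (a loss that *rewards* leaving the
   optimum); the corrected ((1 − IoU) + (1 − e^{−P²})) vanishes iff
   IoU = 1 and P = 0.  Both are implemented; printed is the default
   for fidelity, corrected is the training default.
2. **Penalty geometry**: the printed d-terms compare only widths and
   heights — P is then invariant under translation, and equals 1
   whenever the prediction is smaller than the target in both
   dimensions — while the accompanying prose describes corner-point
   distances.  Both modes exist (`printed`, `corner`); corner is used
   for training.
3. **Focusing factor**: q = e^{−P²} as printed vs q = e^{−P} used
   elsewhere; both available, printed default.

Note the focusing prefactor 3u·e^{−u²} (u = λq, maximum at
u = 1/√2) *decays* as P grows, deliberately down-weighting far misses;
the corrected loss is therefore not monotone in distance even though
its overlap factor is.

## Evaluation

Matching is greedy in descending confidence; a prediction claims the
unmatched same-class ground-truth box of highest IoU ≥ the threshold;
IoU ties break by ground-truth index, confidence ties by prediction
index.  AP integrates the precision–recall curve with the 101-point
monotone-envelope convention (default) or as the exact staircase over
ranking prefixes (used by the oracle tests).  mAP pools detections per
class over all images — the standard protocol — rather than averaging
per-image APs.  mAP@.5:.95 averages thresholds 0.50–0.95 in steps of
0.05.

AP candidates are collected at a low confidence threshold (0.05):
truncating recall before the sweep would understate AP.  Precision,
recall and the per-image count/area errors are reported at the
operating threshold (0.25 by default).

MAPE excludes zero-valued actuals with a warning (a per-image count of
zero has no percentage error); RMSE uses all pairs.  Dice and region
IoU rasterize per-class box unions into binary masks — the only
region definition computable from box-level outputs — and report the
class mean; Dice = 2·IoU/(1+IoU) holds per mask pair.

## Synthetic sections

The generator emulates the annotated corpus the detector targets:
1091 images, 30854 small and 33692 big boxes → Poisson per-image
counts with means 28.28 and 30.88, exactly one cavity and one
perimeter per image, dense arrangement, blurred edges, low contrast,
uneven illumination.

Geometry: a bright tissue disk (radius 0.38–0.45 of the frame, centre
jittered ±2%) on a darker background, a concentric cavity (0.35 of the
stem radius), large bundles rejection-placed in the annulus 0.52–0.78
of the stem radius (radii 8–16 px at the 640 reference), small bundles
in 0.84–0.96 (radii 3–8 px).  Bundles are rotated ellipses (aspect
0.6–1.0); boxes are the analytic bounding boxes of the continuous
ellipses, emitted before any degradation — degradations never move
geometry, so annotations are exact by construction.  Overlap beyond
15% of the bounding circles is rejected; an over-full annulus raises a
packing error naming the constraint.

Degradation order is fixed — render → Gaussian blur (σ 1.5 at 640,
scaled with image size) → multiplicative linear illumination gradient
(±15%) → additive Gaussian texture noise (σ 0.03) → contrast
compression toward mid-grey (factor 0.55) — because the order affects
edge softness, the property that makes the real data hard.  Grayscale
is replicated to three channels.

The **easy preset** exists for CPU smoke training: high contrast, no
blur, sparse large bundles, and bundles that are large relative to the
frame (box area well above 100 px² at the 640² reference), with counts
capped (truncated Poisson, means 5/1) so every seed packs.  What
passing on it shows: the full pipeline — generation, assignment, both
losses, backprop through snake kernels, decoding, matching, AP —
learns and measures correctly end to end.  What it does not show:
performance on real micrographs, which have tissue texture,
sectioning artifacts, staining variation and far denser packing than
the renderer attempts (no phloem/xylem substructure, no histological
realism).

## Training protocol and problem sizes

The full-scale preset follows the reference recipe: Adam, learning
rate 0.01, batch 16, 100 epochs, 640×640 inputs, no augmentation
(optional flips exist behind a flag), constant learning rate — weight
decay, schedule and warmup are unspecified upstream, so none are
added.  Classification BCE is inherited base-architecture machinery,
not a contribution of this package.

The tiny preset — used by the test suite and the acceptance script —
trains the tiny-width model on 100 easy 64×64 scenes for 20 epochs at
learning rate 2e-3 (batch 8, single "small" class) and evaluates a
20-scene holdout.  The reduced rate relative to 0.01 reflects the
small batch and model: at the full rate the tiny run is unstable; at
1e-3 it converges but slowly, and 2e-3 reaches mAP@.5 ≈ 0.5–0.7 in
the 20-epoch budget (~20 s on one CPU core).  Corpus statistics are
measured over 200 generated scenes, where the per-image count means
carry a standard error of ~0.4.

## Numerical choices

* Float32 throughout the network; float64 in the scalar box-geometry
  reference functions and the quantization fits.
* He-normal initialization; batch statistics in batch-norm during
  training, running estimates (momentum 0.1) at evaluation.
* Degenerate rules: α = 0 in CIoU at the 0/0 corner; quantization
  scale 1 for all-zero blocks; KDS ξ = 1, ξ_s = mean(w) when
  Σw_q² = 0; precision/recall defined as 0 on empty denominators; a
  class with no ground truth is excluded from mAP with a warning.
* Ties: matching breaks IoU ties by ground-truth index and confidence
  ties by prediction index; NMS keeps the earlier of equal scores.
* Checkpoints are .npz archives (parameters, batch-norm buffers, JSON
  config snapshot); a run is bit-reproducible from its snapshot and
  seed.

## Known limitations

* The renderer's realism gap (above) means reported tiny-run metrics
  bound pipeline correctness, not field performance.
* Offsets shared per layer cannot adapt the sampling pattern per
  location; an input-conditioned offset field is out of scope.
* The quantized path is exercised functionally but not used during
  training, and brings no runtime benefit in this numpy
  implementation.
* mAP follows the pooled-per-class protocol; per-image AP averaging
  (one possible reading of "average AP of all images") is not
  implemented.
* Single-process CPU only; no augmentation pipeline beyond optional
  flips; no pretrained weights.
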