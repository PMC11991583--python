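# Methods

## The detector

`lgwheatnet` implements a lightweight one-stage, anchor-free detector for
wheat spikes in RGB field imagery, with three growth-stage classes
(`flowerwheat`, `fillingwheat`, `ripewheat`).  The network follows the
small-MobileNetV4 / YOLOv8 lineage:

* **Backbone** — a stem 3x3 stride-2 convolution (3→32) followed by
  inverted-bottleneck stages at strides 4/8/16/32 and an SPPF block at the
  deepest level.  The bottleneck block is the **SeCUIB**: optional initial
  3x3 depthwise convolution (present in stride-2 blocks), 1x1 expansion with
  SiLU, 3x3 mid depthwise convolution carrying the stride with SiLU, channel
  shuffle (2 groups), linear 1x1 projection, squeeze-excitation gate
  (reduction ratio 0.25), and a residual connection when stride is 1 and the
  channel count is unchanged.  Dropping the SE gate and the shuffle (and
  reverting the activation to ReLU) yields the plain UIB baseline block.
* **Neck** — FPN top-down then PAN bottom-up fusion over P3/P4/P5, with
  SeCUIB fusion blocks and **DWDown** downsamplers (1x1 pointwise channel
  adjustment → stride-2 3x3 depthwise convolution → batch normalization).
  The baseline substitutes dense 3x3 stride-2 convolutions.
* **Head** — decoupled regression/classification branches per level.
  **LightDetect** uses a 3x3 group convolution (4 groups) → depthwise
  separable 3x3 → 1x1 prediction; the baseline head uses two dense 3x3
  convolutions per branch.  Box regression is distribution-focal (DFL) with
  16 bins per side, decoded by softmax expectation scaled by the level
  stride around each cell center; the head is anchor-free.

### Stage table and the parameter budget

The published ablation table fixes the trainable-parameter count of every
variant but not the per-stage widths.  The widths in
`network.DEFAULT_WIDTH_CONFIG` (32/64/72/120 across strides 4–32, neck
downsampler widths 75 and 37, standard-head hiddens 86/48, LightDetect
hiddens 124/88/96) were solved so that one shared stage table reproduces all
variant counts exactly and the 2xMAC cost at 640x640 lands on the published
5.0 (full) and 6.8 (baseline) GFLOPs.  Expansion widths grow toward the
stride-32 stage (ratio ~2 early, ~6 late), the usual lightweight-model
trade-off of placing parameters where their FLOP cost is smallest.  The three
module substitutions touch disjoint parameter sets, so variant counts are
exactly additive in the three flags — a structural invariant the test suite
checks.

Counting conventions (they affect the totals, so they are fixed here): all
convolutions followed by batch normalization are bias-free; BN contributes
its two affine vectors; the SE gate uses biased 1x1 convolutions with
reduced width `max(1, round(C/4))`; the final 1x1 prediction convolutions
are biased; DWDown's pointwise stage carries no BN (normalization is the
block's single final step).  FLOPs are 2 x multiply-accumulates of conv and
linear layers only (pooling, BN, activations and upsampling excluded).

## Numerical engine

The network, its training loop and the gradient checks run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`engine.py`): grouped/depthwise convolution via strided patch views and
einsum (a shifted multiply-add fast path for depthwise), train/eval batch
normalization, stride-1 max pooling, nearest upsampling, and an SGD
optimizer with momentum, weight decay and parameter groups.  Arithmetic is
float32; float64 inputs are propagated unchanged so that finite-difference
gradient checks can run at full precision.

## Loss and assignment

The localization loss is `1 − CIoU` with
`CIoU = IoU − ρ²/c² − αv`, `v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))²`,
`α = v/((1−IoU)+v)`; α is treated as a constant under differentiation (the
conventional choice, and the one the finite-difference oracle in the tests
freezes).  Classification is binary cross-entropy on raw logits; box
regression adds a distribution-focal term over the two integer bins
bracketing each normalized target distance.  Targets come from task-aligned
assignment: candidate cells must contain the box center, are ranked by
`score^0.5 · max(CIoU,0)^6`, the top 10 per ground truth become positives,
and conflicts resolve to the highest metric.  Losses are summed and divided
by the total assigned target score (an image with no positives falls back to
the per-cell mean, so an empty image with zero logits pays −log 0.5 per cell
per class).  Loss weights default to 7.5/0.5/1.5 (box/cls/DFL).

## Training recipe

SGD with momentum 0.937 and weight decay 5e-4 on convolution weights only
(BN affine parameters and biases undecayed); lr0 = 0.01 decaying linearly to
lr0·lrf (lrf = 0.01) at the final epoch; 3 warmup epochs during which
weight/BN learning rates ramp from 0, bias learning rates from 0.1, and
momentum from 0.8; 300 epochs and batch 16 by default.  The classification
head bias is initialized to −4.6 (prior probability ≈ 0.01) and the
regression head bias to 1.0 — the standard rare-object prior, which removes
the early flood of false positives.  Only the offline augmentation suite
(noise, brightness, occlusion, rotation, crop, translation, mirror) is used;
no train-time mosaic.  Training is fully seeded and deterministic on CPU.

## Evaluation

Greedy confidence-ordered matching at a given IoU threshold; AP by all-point
precision-envelope integration; mAP50-95 under two protocols — the
conventional ten thresholds 0.50:0.05:0.95 (default `standard10`) and a
91-threshold 0.005-step grid (`paper91`); reported P/R at IoU 0.5 and the
max-F1 confidence.  The counting R² is the squared Pearson correlation
between true and predicted per-image counts — insensitive to constant bias,
unlike the regression coefficient of determination; zero-variance series
report R² = 0 with a warning.  The per-image predicted count is the number
of post-NMS detections above confidence 0.25.

## Sliced inference

Large images are tiled into 256x256 windows with overlap ratio 0.1 (step
floor(256·0.9) = 230); a start that would overrun the border is clamped to
`dim − 256`, so every pixel is covered.  Detections touching an interior
window border are truncated views of objects a neighbouring window sees
whole and are discarded before merging; the pooled remainder is merged by
class-wise greedy NMS.  Region counts use box-center membership with a
half-open (left/top inclusive) tie-break.  With a stub oracle detector on a
synthetic 2000x2000 scene this recovers every object that fits inside a
window, without duplicates.

## Synthetic scenes

The generator (`data_io`) emulates the salient structure of smartphone field
imagery: a multi-scale green clutter background with leaf-like streaks, and
2–8 elongated textured spikes per image (length 14–22 % of the image side,
aspect 2.8–4.2, random orientation) with periodic spikelet texture, awns
fanning from the tip, and class-dependent hue (green-yellow / yellow /
gold).  Each image carries a single growth stage, as a field photograph
taken on one date does.  Ground-truth boxes are exact extents of the
rendered alpha mask (awns included).  Scenes are bit-deterministic per seed.
What it does not emulate: real occlusion statistics, perspective, lighting
variation, inter-plant depth, or label noise — so passing tests demonstrate
implementation correctness and trainability, not field accuracy.

## Problem sizes used in the tests

The smoke/overfit training check memorizes 20 synthetic 128-px scenes with
the full model (batch 5, 150 epochs, train = val) and requires mAP50 ≥ 0.90;
unit tests use 64-px inputs.  The published-scale experiment (640-px inputs,
~40 k instances, 300 epochs) is out of desk scope; the package defaults keep
those values.

## Known limitations

* CPU-only numpy training is orders of magnitude slower than a GPU
  framework; the defaults are faithful but impractical for full-scale runs.
* The SE block's printed formula is degenerate (a scalar mean gate); the
  standard two-layer bottleneck is implemented.
* The baseline (non-SeCUIB) block's activation is not specified anywhere;
  ReLU is used.
* Weight-file size on disk depends on serialization (`.npz` here) and is not
  a target.
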