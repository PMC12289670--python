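# Methods

## Model

The detector follows the familiar single-stage recipe: a cross-stage
partial (CSP) backbone with a spatial-pyramid fast-pooling tail, a
path-aggregation neck (top-down then bottom-up), and a decoupled
anchor-free head predicting, per grid cell, class logits and a discrete
distribution over 16 offsets for each box side. Scale presets `n` and `s`
set depth/width multipliers (0.33, 0.25) and (0.33, 0.50).

**Fused parameterization.** All convolutions carry biases and there is no
batch normalization: the network is built directly in the form a
batch-norm-fused deployment graph would take. This makes the enumerated
learnable-scalar counts equal the conventionally reported "fused" totals —
baseline `s` = 11,156,528 (11.16 M), baseline `n` = 3,151,888 (3.15 M) —
and sidesteps batch-statistics noise at the very small batch sizes used on
CPU. The cost is that training needs the stabilizers listed below.

**SE-MSDWA.** Given input `x` with C channels: `d = dw₅ₓ₅(x)`; three
depthwise strip branches `bᵢ = conv(kᵢ,1)(conv(1,kᵢ)(d))` for k = 5, 9, 17;
`f = conv₁ₓ₁(d + Σ bᵢ)`; `a = SE(f)`; output `x ⊙ a + x`. Branch
aggregation by summation keeps the channel count fixed; the output wiring
(attention applied to the block input, plus residual) is parameter-free and
chosen for stability. The SE reduction ratio of the shipped insertion is
r = 2 and the block sits once at the backbone end (after the pyramid-pooling
tail, C = 512 at scale `s`); both choices were calibrated so the insertion
cost (573,696 parameters ≈ 0.57 M) and the whole-model total land on the
reference figures the design targets. The analytic counter `msdwa_param_count` mirrors the
construction exactly and is tested against enumeration.

**CGFM.** For inputs with C1 and C2 channels (C = C1+C2):
`z = conv₁ₓ₁(cat(x1, x2))`; multi-head self-attention over the spatial
tokens of `z` (4 heads; Q, K, V and output projections are learned 1×1
convolutions with embedding width e); gates `(g1, g2) = split(σ(attn(z)))`;
output `cat(g1 ⊙ x1 + m(x2), g2 ⊙ x2 + m(x1))` where `m` are 1×1
channel-matching convolutions. Output channels equal C1+C2, so the module
is a drop-in for concatenation and the neck graph is otherwise unchanged
(asserted by a topology-diff test). Attention embedding widths are
e = 624 for the 768-channel nodes and e = 320 for the 384-channel nodes —
calibrated against the design's parameter budget (the four nodes together
cost 6,959,392 ≈ 6.96 M). For maps larger than 20 px the attention runs on
stride-2-subsampled tokens with nearest-neighbor restore; this changes no
parameters. The reference per-variant totals are mutually inconsistent by
0.03 M under additivity (0.56 + 6.94 ≠ 7.53), so the calibration pins the
baseline and the full model exactly and accepts ±0.01–0.02 M on the two
single-block ablations.

**Warmup augmentation.** `P(epoch) = min(epoch · 5 / total, 1)` with
0-based epochs, so P = 0 in the first epoch (the claim of a stable start is
literal) and P = 1 from `ceil(total/5)` onwards. P multiplies each
augmentation's own base probability (probability gating); magnitudes are
not scaled. The base pipeline is mosaic (1.0), horizontal flip (0.5), HSV
jitter (0.5) and translate/scale (0.5), all config-driven; disabling mosaic
in the closing epochs is exposed (`close_mosaic_epochs`) and off by
default.

## Training

Task-aligned assignment: candidate anchors lie inside the truth box, the
alignment metric is `cls^0.5 · IoU^6`, top-10 per truth, conflicts resolved
by the larger metric, target scores normalized per truth by its best metric
and IoU. Two robustness details matter at small scale: the candidate floor
is "metric > 0" (any positive floor silently discards all anchors at
initialization, where class probabilities are ~1e-4 and IoU^6 is tiny), and
a truth smaller than the stride-8 anchor spacing — which may contain no
anchor center at all — falls back to its nearest anchor, so every truth
remains learnable.

Loss: binary cross-entropy on class logits against the target scores,
complete-IoU loss on decoded boxes, and distribution-focal loss on the two
bins bracketing each true side offset, weighted 0.5 / 7.5 / 1.5 and
normalized by the summed target scores. Optimizer: Adam at 0.01 with
cosine annealing to 1 % (defaults mirroring the 100-epoch, batch-32,
640-px protocol the architecture is designed for). Because the network is
batch-norm-free, training additionally relies on He-normal weight
initialization with zero biases, a class-prior bias in the classification
head, and global gradient-norm clipping at 10. The best checkpoint by
validation mAP@0.5:0.95 is restored after training.

The overfit smoke configuration used in the test suite is scale `n`,
4 classes, 32 synthetic 96-px images, 30 epochs, batch 2, Adam 1e-3,
augmentation off — chosen so a single CPU finishes in about a minute while
the model memorizes the set (training mAP@0.5 ≈ 0.93).

## Synthetic scenes

The generator emulates the acquisition geometry of a hand-held RGB-D rig:
640×640 frames (any size scales the intrinsics), object distances 30–80 cm,
four growth-stage classes drawn as parametric primitives (pale bud
clusters, white-petal flowers, green→red gradient discs, speckled red
discs) over soil-and-leaf clutter, with exact projected boxes, a z-buffered
millimeter depth map, and a seeded 7:2:1 split. Placement is
rejection-sampled to keep shapes in frame, nearly non-overlapping, and at
least 2 px in projected radius; the object class is drawn before placement
so the realized class mix stays multinomial. Small-frame fixtures (64–96 px)
use closer distances (8–25 cm) so objects stay several pixels wide.

What this does **not** emulate: photometric realism, occlusion by foliage,
variety/lighting variation, label noise, or the difficulty of real orchard
footage. Passing tests therefore certify the machinery — geometry, metric
code, optimization, depth round trips — not field-grade accuracy; the
orchard-scale detection scores such a system reports on real data are out
of reach of any synthetic stand-in and are not claimed.

## Numerical choices

* float32 throughout the network; metric code and back-projection in
  float64.
* IoU of a degenerate (zero-area) box is defined as 0 with a warning;
  0/0 precision and recall are defined as 0; classes without ground truths
  are excluded from mAP with a warning rather than propagating NaN.
* AP uses the 101-point interpolated precision envelope; an exact
  step-integration oracle in the tests bounds the discretization error
  (< 0.01).
* NMS is class-wise greedy at IoU 0.7 (prediction default confidence 0.25);
  ties in confidence are broken by stable sort order.
* Depth aggregation is the median of nonzero values in the central 20 % of
  the box area; zero depth means invalid; stored units × `depth_scale`
  (default 0.1: millimeter maps) give centimeters. Reported distance is
  Euclidean `‖(X,Y,Z)‖` with a raw-Z flag.
* Boxes that collapse to zero area under augmentation are dropped with a
  logged warning.

## Limitations

* CPU-only and sized for small images; a 640-px forward pass works but is
  slow, and full-protocol training (100 epochs, batch 32, 640 px) is not
  practical in this implementation.
* No pretrained weights, no transfer learning, no export formats.
* The multi-head attention in CGFM is quadratic in token count; the stride
  trick caps the cost but coarsens the gates on large maps.
* Scale presets cover `n` and `s` only.
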