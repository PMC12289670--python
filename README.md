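# strawdet

A toolkit for detecting strawberry growth stages in orchard images and
localizing each detection in camera-frame 3-D from an aligned depth map.
It targets agricultural-robotics work — automated flower/fruit thinning and
picking — where all four stages of the crop matter: **bud**, **flower**,
**under-ripe fruit**, **ripe fruit**.

## What is inside

The detector is a CSP-backbone, path-aggregation-neck, anchor-free
single-stage network (scales `n` and `s`), extended with two attention
blocks and a scheduled augmentation policy:

* **SE-MSDWA** — a backbone-tail block combining an initial depthwise
  convolution, three depthwise strip-kernel branches (1×5/5×1, 1×9/9×1,
  1×17/17×1), a pointwise fusion convolution and a squeeze-and-excitation
  stage; the result gates the block input with a residual connection.
* **CGFM** (context-guide fusion) — a drop-in replacement for the four
  channel-concatenation nodes of the neck: multi-head self-attention over
  the spliced map produces sigmoid gates that cross-mix the two pyramid
  levels before re-concatenation (output channels stay `C1 + C2`).
* **Warmup augmentation** — with `N = current_epoch · 5 / total_epochs`,
  the factor `P = min(N, 1)` multiplies every augmentation's base
  probability, so no augmentation fires in epoch 0 and the full default
  pipeline is active from one fifth of training onwards.

Evaluation implements the standard detection metrics

```
P = TP/(TP+FP)    R = TP/(TP+FN)    AP = ∫₀¹ P(R) dR    mAP = Σᵢ APᵢ / N
```

with AP realized as 101-point interpolated precision and `mAP@0.5:0.95`
averaging IoU thresholds 0.50…0.95. RGB-D localization uses the pinhole
model `X = (u−cx)·Z/fx`, `Y = (v−cy)·Z/fy`, with `Z` the median depth over
the central fifth of the box, and reports the Euclidean camera distance.

The network, its training loop (task-aligned assignment, BCE + complete-IoU
+ distribution-focal loss, Adam with cosine annealing) and a small
reverse-mode autodiff core it runs on are implemented in numpy inside this
package (`strawdet.nn`); see `docs/methods.md` for the design notes. A
synthetic-scene generator (`strawdet.scenes`) renders parametric
growth-stage objects with exact labels, depth maps and known 3-D positions
so every stage of the pipeline is testable without field data.

## Worked example

Parameter counts identify the architecture variants exactly
(`python examples/count_parameters.py`):

```
baseline, scale n              3.15 M  =  3,151,888
baseline, scale s             11.16 M  = 11,156,528
+ SE-MSDWA (backbone end)     11.73 M  = 11,730,224  (+0.57 M over baseline)
+ CGFM (4 neck nodes)         18.12 M  = 18,115,920  (+6.96 M over baseline)
full model (both blocks)      18.69 M  = 18,689,616  (+7.53 M over baseline)
```

3-D localization on a rendered scene (`python examples/rgbd_localization.py`):

```
true position   : X=  10.00  Y=  -5.00  Z=  40.00 cm
recovered       : X=  10.03  Y=  -4.97  Z=  40.00 cm
camera distance : 41.54 cm
round-trip error: 0.047 cm
```

The first block says the full attention-augmented model costs 7.53 M
parameters over the baseline; the second shows a detection back-projected
through the depth map to within half a millimeter of its true position.
The other scripts in `examples/` walk through the warmup schedule, dataset
rendering, metric computation and a short training run. A thin CLI wraps
the same functions:

```bash
strawdet make-fixtures --n 100 --out dataset --seed 7
strawdet count-params --scale s --se-msdwa --cgfm
strawdet train dataset --epochs 30 --out model.npz
strawdet detect model.npz dataset/images/test/*.png --out preds.jsonl
strawdet locate preds.jsonl --depth-dir dataset/depth/test --config cfg.yaml
strawdet evaluate preds.jsonl dataset --split test
```

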