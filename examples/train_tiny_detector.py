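"""Train a tiny detector end to end on synthetic scenes.

A scale-n, 4-class model is trained briefly on 64-px synthetic images with
the warmup augmentation schedule enabled, then scored on its own training
split. A short run like this only demonstrates the wiring (loss decreasing,
schedule ramping, metrics computable); memorization takes ~30 epochs.
"""

import tempfile
from pathlib import Path

from strawdet import ModelConfig, TrainConfig, build_model, make_dataset
from strawdet.train import _load_split_arrays, evaluate_model, train

root = Path(tempfile.mkdtemp()) / "tinyset"
manifest = make_dataset(12, seed=11, out_dir=root, image_size=64,
                        objects_per_image=(1, 2), depth_range_cm=(8, 20))

model = build_model(ModelConfig(scale="n", num_classes=4, use_warmup=True), seed=0)
cfg = TrainConfig(epochs=5, batch_size=4, image_size=64, lr=1e-3, seed=0)
model, history = train(model, manifest, cfg, val_interval=1000)

print("epoch  loss    warmup-P  augmentations fired")
for h in history:
    print(f"{h['epoch']:5d}  {h['total']:6.3f}  {h['warmup_p']:8.2f}  "
          f"{h['augmentations_fired']:5d}")

images, labels = _load_split_arrays(manifest, "train")
report = evaluate_model(model, images, labels)
print(f"\ntraining-split mAP@0.5 after {cfg.epochs} epochs: {report['map50']:.3f}")
print("The warmup column shows augmentation ramping in over the first fifth")
print("of training (epoch 0 fires none). A run this short typically still")
print("scores near-zero mAP; memorizing a 32-image set takes ~30 epochs")
print("without augmentation (see docs/methods.md for that recipe).")
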