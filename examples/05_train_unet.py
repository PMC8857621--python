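"""Train a desk-scale U-Net to reproduce the Niblack ground truth.

Phantom scans are flattened, resampled to the 224x896 network grid,
binarized into 3-category ground truth (lumen / interstitial / sclera,
with the sclera painted (127,0,0) into the input), and tiled into four
224x224 tiles each.  A 16-filter U-Net is trained with Adam and
cross-entropy, then evaluated on reassembled full-width scans from
held-out phantoms.  Takes a few minutes on one CPU.
"""

import numpy as np

from choroseg.core import Category
from choroseg.dataset import tile_image
from choroseg.metrics import accuracy, confusion, cvi
from choroseg.network import build_unet, desk_profile, predict_full, train
from choroseg.pipeline import phantom_ground_truth_corpus

train_pairs, _ = phantom_ground_truth_corpus(12, seed=0)
_, eval_scans = phantom_ground_truth_corpus(3, seed=500)
print(f"{len(train_pairs)} training tiles from 12 scans; "
      f"{len(eval_scans)} held-out scans")

cfg = desk_profile(seed=0, epochs=3)
model = build_unet(cfg)
print(f"u-net filters {model.filter_counts} (doubling per pooling stage)")
model, history = train(model, train_pairs, None, cfg)
for rec in history:
    print(f"epoch {rec.epoch}: training loss {rec.train_loss:.4f}")

for i, (image, labels) in enumerate(eval_scans):
    pred = predict_full(model, tile_image(image))
    cm = confusion(pred, labels)
    print(f"scan {i}: total accuracy {accuracy(cm):.3f}, "
          f"sclera {accuracy(cm, Category.SCLERA):.3f}, "
          f"CVI pred {cvi(pred):.2f}% vs ground truth {cvi(labels):.2f}%")
print("(sclera is near-perfect because the painted mask makes it a "
      "highlighted region)")
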