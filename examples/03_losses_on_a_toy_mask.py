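"""Weighted Dice loss vs the boundary-emphasizing variant on a toy case.

FBDL weighs classes by inverse frequency (so sparse, spatially complex
VAT counts as much as the large SAT ring) and doubles the weight of
voxels within one voxel of a reference label boundary.  The demo places
the same number of erroneous voxels on the boundary band and strictly
inside a structure: only FBDL tells them apart.
"""

import numpy as np

from adiposeg.losses import (LossConfig, boundary_weights, fbdl,
                             weighted_dice_loss)

labels = np.zeros((8, 8, 8), dtype=int)
labels[1:7, 1:7, 1:7] = 1                      # a SAT block
band = boundary_weights(labels, 1, 2.0) > 1
interior = (labels == 1) & ~band


def corrupt(where, k=6):
    probs = np.stack([(labels == l) for l in range(3)]).astype(float)
    for i, j, z in np.argwhere(where)[:k]:
        probs[:, i, j, z] = (0.0, 0.0, 1.0)    # SAT voxel called VAT
    return probs


cfg = LossConfig(type="FBDL", class_weight_mode="manual",
                 boundary_multiplier=2.0)
print(f"WDL,  errors on boundary: "
      f"{weighted_dice_loss(corrupt(band & (labels == 1)), labels):.4f}")
print(f"WDL,  errors interior:    "
      f"{weighted_dice_loss(corrupt(interior), labels):.4f}")
print(f"FBDL, errors on boundary: "
      f"{fbdl(corrupt(band & (labels == 1)), labels, cfg):.4f}")
print(f"FBDL, errors interior:    "
      f"{fbdl(corrupt(interior), labels, cfg):.4f}")
print()
print("WDL scores both corruptions identically; FBDL penalizes the")
print("boundary-band errors more, which is what pushes a model to refine")
print("exactly the voxels where adipose segmentations typically fail.")
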