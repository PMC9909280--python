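"""C-peak deletion augmentation and the loss-weight / cutoff grid search.

First turns double-peak traces into only-T traces by replacing the C-peak
region with a cubic-spline background bridge (the augmentation used to
mass-produce class-3 training data), then runs a reduced weight x cutoff
cross-experiment for the segmenter's combined WBCE+DSC loss.
"""

import numpy as np

from lfianet import (
    SynthConfig, TrainConfig, generate_dataset, mask_runs, remove_c_peak,
    split_dataset,
)
from lfianet.models import SegmenterConfig
from lfianet.training import grid_search

# --- augmentation ----------------------------------------------------------
dataset = generate_dataset(SynthConfig(counts=(0, 0, 0, 60), seed=13))
augmented = [remove_c_peak(t) for t in dataset[:3]]
for before, after in zip(dataset, augmented):
    c_run, t_run = mask_runs(before.mask)
    t_equal = np.array_equal(before.values[t_run[0]:t_run[1]],
                             after.values[t_run[0]:t_run[1]])
    print(f"class {before.label} -> {after.label}: C run {c_run} spline-filled,"
          f" T region bitwise unchanged: {t_equal}")

# --- reduced grid search ---------------------------------------------------
train, val = split_dataset(dataset, 0.8, seed=13)
grid = grid_search(
    train, val,
    weight_ratios=((0.6, 0.4), (0.4, 0.6)),
    cutoffs=(0.5, 0.6),
    config=TrainConfig(loss="WBCE+DSC", epochs=10, seed=13),
    model_config=SegmenterConfig(encoder_features=(8, 16, 16, 32)),
)
print("\nvalidation IoU by WBCE weights (rows w0:w1) and cutoff (columns):")
print(grid.round(4))
print("-> one segmenter is trained per weight ratio; the cutoff is applied "
      "at inference, as in the full 5x5 experiment.")
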