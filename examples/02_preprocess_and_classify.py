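"""Train the peak-shape classifier on a small synthetic set.

Preprocesses raw traces into the two-channel (min-max + log) representation,
trains the 1D CNN for a few epochs, and reports validation accuracy and the
confusion matrix (rows = predicted class, columns = true class).

A short demonstration run; the full surrogate benchmark (30 epochs,
1,230 traces, accuracy ~99.6%) lives in scripts/acceptance.py.
"""

import numpy as np

from lfianet import (
    SynthConfig, TrainConfig, evaluate, generate_dataset, split_dataset,
    to_model_input, train_classifier,
)

dataset = generate_dataset(SynthConfig(counts=(60, 60, 60, 90), seed=3))
train, val = split_dataset(dataset, ratio=0.8, seed=3)
print(f"training on {len(train)} traces, validating on {len(val)}")

x = to_model_input(dataset[0].values)
print(f"model input: {x.shape[0]} points x {x.shape[1]} channels, "
      f"range [{x.min():.2f}, {x.max():.2f}]")

model, history = train_classifier(train, val, TrainConfig(epochs=8, seed=3))
print(f"\nbest validation accuracy {history.best_metric:.4f} "
      f"at epoch {history.best_epoch + 1} of {len(history.val_metric)}")

report = evaluate(model, val)
print("confusion matrix (rows = predicted class 1..4, cols = true):")
print(np.array(report["confusion"]))
print("-> off-diagonal counts are the misclassified validation traces.")
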