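"""Build a synthetic labeled EEG dataset and inspect its structure.

Generates the binary (normal vs interictal) layout: per-class
multichannel recordings, 158-sample windows shuffled into one continuous
labeled recording, lag-framed instances, a contiguous 70/10/20 split,
and train-fitted min-max scaling.
"""

import numpy as np

from neurotune import make_synthetic_dataset

frame, scaling = make_synthetic_dataset(
    n_classes=2, windows_per_class=25, channels=8, seed=42
)

print(f"instances: {len(frame)} of shape (lags={frame.lags}, channels={frame.channels})")
for tag in ("train", "val", "test"):
    X, y = frame.subset(tag)
    print(f"  {tag:<5} n={len(y):5d}  class counts={np.bincount(y).tolist()}")
print(f"per-channel train minima: {np.round(scaling.minimum, 2).tolist()}")
print("labels: 0 = normal background, 1 = anomalous (interictal)")
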