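"""Build the fused transfer feature set from raw segments.

Forest class probabilities (f1..f5, cross-fitted on the training side)
are concatenated with the recurrent network's class-probability head
(f6..f10).  Every probability block sums to 1 per row.
"""

import numpy as np

from rfgr import (
    RFGRConfig,
    SynthConfig,
    generate_balanced_dataset,
    generate_transfer_features,
    stratified_split,
)

dataset = generate_balanced_dataset(5, SynthConfig(master_seed=0))
train, test = stratified_split(dataset, train_fraction=0.8, seed=0)

config = RFGRConfig(seed=0)  # 100 trees, 64 GRU units, fused mode
train_fs, test_fs, extractors = generate_transfer_features(train, test, config)

print(f"train features: {train_fs.X.shape}, test features: {test_fs.X.shape}")
print("columns:", dict(zip(train_fs.feature_names, train_fs.provenance)))
print("first test row:", np.round(test_fs.X[0], 3))
print(
    "row sums (forest block, recurrent block):",
    round(float(test_fs.X[0, :5].sum()), 6),
    round(float(test_fs.X[0, 5:].sum()), 6),
)
# Each block is a proper probability distribution over the five classes;
# a confident row concentrates mass on one class in both blocks.
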