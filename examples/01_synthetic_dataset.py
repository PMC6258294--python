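"""Generate the default synthetic study dataset and inspect its makeup.

Builds 166 'xenomiR-like' and 942 'non-xenomiR-like' sequences whose
classes differ in C/U content, CAG motif frequency and length, plus an
unlabeled pool of 500 with hidden ground truth.
"""

import numpy as np

from xenomir import feature_matrix, generate_dataset, table1_like_config

cfg = table1_like_config(seed=1)
dataset, pool, truth = generate_dataset(cfg)

print(f"positives: {len(dataset.positives)}  negatives: "
      f"{len(dataset.negatives)}  pool: {len(pool)}")

pos_X = feature_matrix(dataset.positives)
neg_X = feature_matrix(dataset.negatives)
for feat in ("C", "U", "CAG", "length"):
    print(f"  mean {feat:>6}: positives {pos_X[feat].mean():.4f}  "
          f"negatives {neg_X[feat].mean():.4f}")

# The directions mirror the real xenomiR contrasts: positives are
# C-richer, U-poorer, CAG-richer and shorter than negatives.
print(f"pool ground-truth positive fraction: "
      f"{np.mean(list(truth.values())):.2f}")
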