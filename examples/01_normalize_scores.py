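"""Thresholding and normalizing scores from models with unlike distributions.

Two simulated models score the same 10,000 candidate pairs, one with a
left-skewed distribution around 50, one right-skewed around -3: their raw
scores are not comparable. Keeping only each model's top 1% and normalizing
inside that retained set puts both on [0, 1] while preserving each model's
internal ordering.
"""

import numpy as np
from scipy import stats

from kgfuse import normalize_table
from kgfuse.scores import ScoreTable

rng = np.random.default_rng(0)
pairs = [(f"drug_{i:05d}", "disease_0") for i in range(10_000)]

models = {
    "left_skewed": stats.skewnorm.rvs(-6, loc=50, scale=8, size=10_000,
                                      random_state=rng),
    "right_skewed": stats.skewnorm.rvs(6, loc=-3, scale=0.5, size=10_000,
                                       random_state=rng),
}

for name, raw in models.items():
    table = ScoreTable.from_pairs(name, pairs, raw)
    print(f"{name}: raw scores span [{raw.min():.2f}, {raw.max():.2f}]")
    for method in ("minmax", "sigmoid", "rank"):
        topk = normalize_table(table, percentile=99.0, method=method)
        norm = topk.frame["normalized"]
        print(
            f"  top 1% ({topk.k_kept} pairs), {method:7s}: "
            f"normalized in [{norm.min():.3f}, {norm.max():.3f}], "
            f"median {norm.median():.3f}"
        )

# The k_kept=100 retained pairs per model are now directly comparable across
# models: 1.0 is each model's most confident prediction, 0.0 its weakest
# retained one, whatever interval the raw scores lived in.
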