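"""Compare the three filter selectors on one binary task.

Ranking ignores redundancy; FCBF removes features dominated by a
better-ranked, more-similar feature; mRMR trades relevance against mean
redundancy with the already-selected set.
"""

import numpy as np

from iefs import fcbf_select_n, mrmr_select, rank_by_relevance

rng = np.random.default_rng(0)
n = 120
y = rng.integers(0, 2, n).astype(bool)
signal = y.astype(float) * 2
X = np.column_stack([
    signal + rng.normal(scale=0.8, size=n),   # informative
    signal + rng.normal(scale=0.8, size=n),   # informative, partly redundant
    X0 := signal + rng.normal(scale=0.8, size=n),
    X0 + rng.normal(scale=0.05, size=n),      # near-copy of gene 2
    rng.normal(size=n),                       # noise
    rng.normal(size=n),                       # noise
])

print("gene 3 is a near-copy of gene 2; genes 4-5 are noise\n")
ranked = rank_by_relevance(X, y, n=4)
print("ranking top-4:", ranked.feature_indices.tolist(),
      " (keeps the redundant copy)")

fcbf = fcbf_select_n(X, y, n=4)
print("FCBF (n=4):   ", fcbf.feature_indices,
      f" short={fcbf.short}  (redundant copy eliminated)")

mrmr = mrmr_select(X, y, n=4, window=6)
print("mRMR (n=4):   ", mrmr.feature_indices,
      " (selection order; copy penalised by redundancy term)")
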