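"""Digital re-normalization: possibly-gapped histograms on a bimodal feature.

Builds a small mixed-type matrix (a bimodal continuous feature with extreme
stragglers, plus a binary flag), re-normalizes it onto the common 0-9 code
range, and prints each feature's histogram structure.
"""

import numpy as np
import pandas as pd

from entroflow import FeatureSpec, RawDataMatrix, renormalize_matrix

rng = np.random.default_rng(0)
body = np.concatenate([rng.normal(3500, 80, 60), rng.normal(3900, 80, 60)])
head_size = np.concatenate([[2700.0, 2730.0], body, [4500.0, 4540.0]])
flag = (head_size > 3700).astype(int)

frame = pd.DataFrame(
    {"head_size": head_size, "large_flag": flag},
    index=[f"s{i:03d}" for i in range(len(head_size))],
)
raw = RawDataMatrix(frame, [
    FeatureSpec("head_size", "continuous", "covariate"),
    FeatureSpec("large_flag", "binary", "covariate"),
])

coded, hists = renormalize_matrix(raw)

h = hists["head_size"]
print(f"head_size: {h.n_bins} bins, {len(h.gaps)} gaps")
for (lo, hi), c, code in zip(h.bin_edges, h.counts, h.codes):
    print(f"  bin [{lo:8.1f}, {hi:8.1f}]  count {c:3d}  -> code {code}")
for lo, hi in h.gaps:
    print(f"  gap [{lo:8.1f}, {hi:8.1f}]")
print("large_flag codes:", sorted(coded.codes["large_flag"].unique()))

# What to look for: the extreme small/large stragglers sit in their own
# bins flanked by gaps (empty stretches of the measurement axis), the
# central mass is split by the piecewise-linear ECDF fit, and the binary
# flag is coded by reference to its anchor (the continuous feature),
# landing near the anchor's mean code within each flag level.
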