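"""Mutual conditional entropy: measuring nonlinear feature dependency.

Generates 2 planted synergistic feature groups (features within a group
share a latent code) and prints the pairwise mutual conditional-entropy
matrix: near 0 = strong categorical correspondence, near 1 = independence.
"""

import numpy as np

from entroflow import entropy_matrix, make_synergistic_codes

coded, truth = make_synergistic_codes(
    n_subjects=300, n_groups=2, features_per_group=3, noise=0.4, seed=1
)
xi = entropy_matrix(coded)

print("mutual conditional-entropy matrix (features G<group>F<index>):")
print(xi.to_dataframe().round(2).to_string())

m = len(truth)
within = [xi.values[i, j] for i in range(m) for j in range(i + 1, m)
          if truth[i] == truth[j]]
between = [xi.values[i, j] for i in range(m) for j in range(i + 1, m)
           if truth[i] != truth[j]]
print(f"\nmean within-group entry : {np.mean(within):.2f}  (synergistic)")
print(f"mean cross-group entry  : {np.mean(between):.2f}  (antagonistic)")

# Entries well below 1 inside each planted group mean knowing one
# feature's code predicts the other's; cross-group entries near 1 mean
# the groups carry independent mechanisms.
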