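"""End-to-end information flow: linking response to covariate mechanisms.

Generates a planted dataset — a 2-feature response with 2 subject
clusters, one covariate group whose 3 subject clusters map exclusively
onto the response clusters, and one unlinked group — runs the whole
pipeline and prints the confirmed flow.
"""

import numpy as np

from entroflow import (
    CovariateGroupSpec,
    FixtureConfig,
    build_information_flow_raw,
    make_planted_dataset,
)

cfg = FixtureConfig(
    n_subjects=100,
    n_response_features=2,
    n_response_clusters=2,
    n_latent_clusters=3,
    response_map={0: 0, 1: 1, 2: 1},
    noise=0.3,
    covariate_groups=[
        CovariateGroupSpec(n_features=4, n_clusters=3, linked=True,
                           exclusivity=1.0),
        CovariateGroupSpec(n_features=4, n_clusters=2, linked=False),
    ],
    seed=0,
)
resp, cov, truth = make_planted_dataset(cfg)
result = build_information_flow_raw(resp, cov, rng_seed=0)

print("covariate feature groups found:", result.covariate_groups)
flow = result.flows[0]
print(f"\nresponse entropy H(Y) = {flow.links[0].response_entropy:.3f}")
for link in flow.links:
    print(f"\n{link.name}: overall H(Y|X) = {link.overall_entropy:.3f}")
    for k in link.covariate_comp.clusters:
        print(f"  cluster {k} (size {link.cluster_sizes[k]:2d}): "
              f"H = {link.per_cluster_entropy[k]:.3f}, "
              f"p = {link.pvalues[k]:.4f}, "
              f"majority response label = {link.majority_labels[k]}")
print(f"\nserial weights    : {np.round(flow.weights, 3)}")
print(f"serial error rate : {flow.serial_error:.3f}")

# The linked group's link shows per-cluster entropies near 0 with tiny
# p-values — each of its subject clusters is (nearly) pure in one
# response cluster, the exclusive linkage the method looks for.  The
# unlinked group's overall entropy stays near H(Y): it carries no
# information about the response, and its serial weight is small.
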