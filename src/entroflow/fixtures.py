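"""Seeded generators of datasets with the structure the method assumes.

Real applications of this protocol involve small tabular studies (tens to
hundreds of subjects, a handful to a dozen features of mixed types) with
three kinds of planted structure: synergistic feature groups (features
sharing a latent mechanism), subject clusters, and an exclusive linkage
from response-side clusters to covariate-side clusters.  The generators
here plant exactly those structures with controllable noise and return the
ground truth alongside, so that every pipeline stage can be scored without
external downloads.  All generators are bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .renormalize import (
    DEFAULT_CODE_RANGE,
    CodedMatrix,
    FeatureSpec,
    RawDataMatrix,
)


@dataclass
class CovariateGroupSpec:
    """One synergistic covariate feature group.

    ``linked`` groups derive their subject clusters from the latent fine
    partition through ``linkage_map`` (latent cluster -> covariate cluster;
    default: latent z maps to z mod n_clusters); a subject follows the map
    with probability ``exclusivity`` and otherwise lands in a uniformly
    random cluster, so exclusivity 0 is full independence.  Unlinked
    groups draw independent subject clusters.
    """

    n_features: int = 4
    n_clusters: int = 2
    linked: bool = False
    exclusivity: float = 1.0
    linkage_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.exclusivity <= 1.0:
            raise ValueError("exclusivity must lie in [0, 1]")


@dataclass
class FixtureConfig:
    """Study conditions for :func:`make_planted_dataset`.

    Defaults emulate the scale of the method's demonstration datasets:
    a hundred subjects, a two-feature response group with two subject
    clusters, and two covariate groups of four features each, the first
    linked exclusively to the response.  ``noise`` is the within-cluster
    standard deviation relative to the cluster separation (cluster centers
    sit ``separation`` standard deviations apart).  ``binary_features``
    converts that many covariate features (one per group, round-robin) to
    binary labels by thresholding, exercising the anchor-coding path.

    Subjects first receive a *latent* fine cluster (``n_latent_clusters``,
    defaulting to the response cluster count); the response clusters are a
    coarsening of it through ``response_map`` (latent -> response cluster,
    default z mod n_response_clusters) and linked covariate groups map the
    same latent through their own linkage maps.  This lets, e.g., three
    exclusive covariate clusters cover two response clusters.
    """

    n_subjects: int = 100
    n_response_features: int = 2
    n_response_clusters: int = 2
    n_latent_clusters: int | None = None
    response_map: dict[int, int] | None = None
    separation: float = 6.0
    covariate_groups: list[CovariateGroupSpec] = field(
        default_factory=lambda: [
            CovariateGroupSpec(n_features=4, n_clusters=2, linked=True,
                               exclusivity=1.0),
            CovariateGroupSpec(n_features=4, n_clusters=2, linked=False),
        ]
    )
    noise: float = 0.5
    binary_features: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_response_clusters > self.n_subjects:
            raise ValueError("more response clusters than subjects")
        for g in self.covariate_groups:
            if g.n_clusters > self.n_subjects:
                raise ValueError("more covariate clusters than subjects")


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Near-balanced cluster labels in a random subject order."""
    base = np.repeat(np.arange(k), n // k)
    extra = rng.choice(k, size=n - base.size, replace=False) if n - base.size else \
        np.empty(0, dtype=int)
    labels = np.concatenate([base, extra]).astype(int)
    rng.shuffle(labels)
    return labels


def make_planted_dataset(
    cfg: FixtureConfig,
) -> tuple[RawDataMatrix, RawDataMatrix, dict]:
    """Generate raw response and covariate matrices with planted structure.

    Subjects receive a response cluster; each covariate group receives
    subject clusters per its linkage spec.  Every feature in a group is the
    group's cluster center (centers ``separation`` apart on a latent axis)
    plus independent unit-scale Gaussian noise times ``noise``; across
    groups the latents are independent unless linked through the response.
    Returns the two RawDataMatrix objects and a ground-truth dict with the
    response subject clusters, the per-group covariate subject clusters and
    the covariate feature-group partition.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subject_ids = [f"s{i:04d}" for i in range(n)]

    n_latent = cfg.n_latent_clusters or cfg.n_response_clusters
    latent = _balanced_labels(n, n_latent, rng)
    resp_map = cfg.response_map or {
        z: z % cfg.n_response_clusters for z in range(n_latent)
    }
    resp_clusters = np.array([resp_map[z] for z in latent], dtype=int)

    resp_cols, resp_specs = {}, []
    for f in range(cfg.n_response_features):
        centers = np.arange(cfg.n_response_clusters) * cfg.separation
        resp_cols[f"R{f}"] = centers[resp_clusters] + \
            rng.normal(0, max(cfg.noise, 1e-9), n)
        resp_specs.append(FeatureSpec(f"R{f}", "continuous", "response"))

    cov_cols, cov_specs = {}, []
    group_clusters = {}
    feature_group_of = {}
    binary_budget = cfg.binary_features
    for gi, g in enumerate(cfg.covariate_groups):
        if g.linked:
            mapping = g.linkage_map or {
                z: z % g.n_clusters for z in range(n_latent)
            }
            labels = np.array([mapping[z] for z in latent], dtype=int)
            if g.exclusivity < 1.0 and g.n_clusters > 1:
                # non-exclusive subjects land uniformly at random, so
                # exclusivity 0 means full independence from the response
                stray = rng.random(n) > g.exclusivity
                labels[stray] = rng.integers(0, g.n_clusters, size=int(stray.sum()))
        else:
            labels = _balanced_labels(n, g.n_clusters, rng)
        group_clusters[gi] = labels
        centers = np.arange(g.n_clusters) * cfg.separation
        for f in range(g.n_features):
            name = f"G{gi}F{f}"
            values = centers[labels] + rng.normal(0, max(cfg.noise, 1e-9), n)
            if binary_budget > 0 and f == g.n_features - 1:
                binary_budget -= 1
                cut = np.median(values)
                cov_cols[name] = (values > cut).astype(int)
                cov_specs.append(FeatureSpec(name, "binary", "covariate"))
            else:
                cov_cols[name] = values
                cov_specs.append(FeatureSpec(name, "continuous", "covariate"))
            feature_group_of[name] = gi

    resp = RawDataMatrix(
        pd.DataFrame(resp_cols, index=subject_ids), resp_specs
    )
    cov = RawDataMatrix(
        pd.DataFrame(cov_cols, index=subject_ids), cov_specs
    )
    truth = {
        "latent_clusters": latent,
        "response_clusters": resp_clusters,
        "covariate_clusters": group_clusters,
        "feature_groups": feature_group_of,
    }
    return resp, cov, truth


def make_synergistic_codes(
    n_subjects: int = 200,
    n_groups: int = 3,
    features_per_group: int = 5,
    noise: float = 0.5,
    code_range: int = DEFAULT_CODE_RANGE,
    seed: int | None = None,
) -> tuple[CodedMatrix, np.ndarray]:
    """Coded matrix whose features form planted synergistic groups.

    Each group carries an independent latent code per subject (uniform on
    the common range); every feature in the group is the latent plus
    independent rounded-Gaussian code noise with standard deviation
    ``noise``, clipped to the range.  Within-group feature pairs therefore
    have low mutual conditional entropy while cross-group pairs are
    independent (entropy near 1).  Returns the matrix and the true group
    index per feature.
    """
    rng = np.random.default_rng(seed)
    cols, specs, truth = {}, [], []
    for g in range(n_groups):
        latent = rng.integers(0, code_range, size=n_subjects)
        for f in range(features_per_group):
            delta = np.round(rng.normal(0, noise, size=n_subjects)).astype(int)
            name = f"G{g}F{f}"
            cols[name] = np.clip(latent + delta, 0, code_range - 1)
            specs.append(FeatureSpec(name, "discrete", "covariate"))
            truth.append(g)
    ids = [f"s{i:04d}" for i in range(n_subjects)]
    coded = CodedMatrix(pd.DataFrame(cols, index=ids), specs, code_range)
    return coded, np.array(truth)


def make_checkerboard_matrix(
    n_rows: int = 60,
    n_cols: int = 12,
    row_blocks: int = 2,
    col_blocks: int = 3,
    noise: int = 1,
    code_range: int = DEFAULT_CODE_RANGE,
    seed: int | None = None,
) -> tuple[CodedMatrix, dict]:
    """Block-constant coded matrix plus discrete noise, with ground truth.

    Rows and columns are split into equal blocks; each (row, column) block
    gets a constant code spread over the common range, to which integer
    noise uniform on [-noise, noise] is added and clipped.  Returns the
    matrix and the true row/column block labels.
    """
    if n_rows % row_blocks or n_cols % col_blocks:
        raise ValueError("blocks must divide the matrix dimensions")
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(row_blocks), n_rows // row_blocks)
    col_labels = np.repeat(np.arange(col_blocks), n_cols // col_blocks)
    n_blocks = row_blocks * col_blocks
    block_codes = np.floor(
        np.arange(n_blocks) * (code_range - 1) / max(n_blocks - 1, 1) + 0.5
    ).astype(int)
    # interleave so adjacent blocks differ strongly
    block_codes = block_codes[np.argsort(np.argsort((np.arange(n_blocks) * 7) % n_blocks))]
    base = block_codes[(row_labels[:, None] * col_blocks + col_labels[None, :])]
    if noise > 0:
        base = base + rng.integers(-noise, noise + 1, size=base.shape)
    codes = np.clip(base, 0, code_range - 1)
    ids = [f"r{i:03d}" for i in range(n_rows)]
    names = [f"c{j:02d}" for j in range(n_cols)]
    specs = [FeatureSpec(nm, "discrete", "covariate") for nm in names]
    coded = CodedMatrix(pd.DataFrame(codes, index=ids, columns=names), specs,
                        code_range)
    return coded, {"row_labels": row_labels, "col_labels": col_labels}
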