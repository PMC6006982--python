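"""Information flows: linking response-side to covariate-side subject clusterings.

An information flow maps the subject clustering induced by a synergistic
group of response features onto the subject clusterings induced by a series
of synergistic covariate feature groups.  Each response/covariate pairing
is scored by the directed conditional entropy of the response labels within
every covariate cluster: a cluster whose members all carry one response
label has zero entropy — the exclusive linkage the method looks for.
Observed per-cluster entropies are confirmed against a resampling null
(response labels drawn without replacement, i.e. permuted, across subjects)
and summarized by majority-rule error rates; a serial flow over several
covariate groups combines per-link majority votes with weights inversely
proportional to each link's overall conditional entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dcg import DCGConfig, DCGTree, DistanceMatrix, build_dcg_tree
from .data_mechanics import CouplingGeometry, run_data_mechanics
from .entropy import (
    ClusteringComposition,
    _entropy_from_counts,
    conditional_entropy_by_cluster,
    entropy_matrix,
    shannon_entropy,
)
from .renormalize import CodedMatrix, RenormalizeConfig, renormalize_matrix

logger = logging.getLogger(__name__)


@dataclass
class FlowLink:
    """One response-to-covariate pairing with per-cluster directed entropies."""

    response_comp: ClusteringComposition
    covariate_comp: ClusteringComposition
    per_cluster_entropy: dict
    overall_entropy: float
    response_entropy: float
    majority_labels: dict
    pvalues: dict | None = None
    name: str = ""

    @property
    def cluster_sizes(self) -> dict:
        c = self.covariate_comp
        return {k: int(s) for k, s in zip(c.clusters, c.sizes)}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "response_entropy": self.response_entropy,
            "overall_entropy": self.overall_entropy,
            "per_cluster_entropy": {str(k): v for k, v in
                                    self.per_cluster_entropy.items()},
            "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
            "majority_labels": {str(k): str(v) for k, v in
                                self.majority_labels.items()},
            "pvalues": None if self.pvalues is None else
                       {str(k): v for k, v in self.pvalues.items()},
        }


@dataclass
class InformationFlow:
    """A response composition linked to an ordered series of covariate links.

    Links are ordered by ascending overall conditional entropy (most
    informative first); per-link weights are proportional to
    1 / (overall entropy + epsilon) and normalized to sum to one.
    """

    response_group: list[str]
    links: list[FlowLink]
    epsilon: float = 1e-6
    serial_error: float | None = None

    def __post_init__(self) -> None:
        if not self.links:
            raise ValueError("an information flow needs at least one link")
        self.links = sorted(self.links, key=lambda l: l.overall_entropy)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([1.0 / (l.overall_entropy + self.epsilon) for l in self.links])
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "response_group": self.response_group,
            "links": [l.to_dict() for l in self.links],
            "weights": self.weights.tolist(),
            "serial_error": self.serial_error,
        }


def flow_entropy(
    resp_comp: ClusteringComposition,
    cov_comp: ClusteringComposition,
    name: str = "",
) -> FlowLink:
    """Directed response-to-covariate conditional entropies, per covariate cluster.

    For each covariate cluster k, the entropy of the response labels among
    its members; the overall value is the size-weighted sum.  A low overall
    value signals a strong associative pattern; a zero per-cluster value
    means the cluster is response-pure (exclusive linkage).  Majority labels
    per cluster are recorded, ties broken toward the globally more frequent
    response label.
    """
    per = conditional_entropy_by_cluster(resp_comp, cov_comp)
    p = cov_comp.sizes / cov_comp.n
    overall = float(sum(pk * per[k] for pk, k in zip(p, cov_comp.clusters)))
    h_resp = shannon_entropy(resp_comp)

    global_counts = {
        lab: int(c)
        for lab, c in zip(*np.unique(resp_comp.labels, return_counts=True))
    }
    majority = {}
    for k in cov_comp.clusters:
        members = cov_comp.members(k)
        labs, counts = np.unique(resp_comp.labels[members], return_counts=True)
        top = counts.max()
        tied = [l for l, c in zip(labs, counts) if c == top]
        if len(tied) > 1:
            tied.sort(key=lambda l: -global_counts[l])
            logger.info("majority tie in cluster %r broken toward %r", k, tied[0])
        majority[k] = tied[0]

    return FlowLink(
        response_comp=resp_comp,
        covariate_comp=cov_comp,
        per_cluster_entropy=per,
        overall_entropy=overall,
        response_entropy=h_resp,
        majority_labels=majority,
        name=name,
    )


def resampling_pvalues(
    resp_labels,
    cov_comp: ClusteringComposition,
    n_sims: int = 1000,
    rng_seed: int | None = None,
) -> dict:
    """Per-cluster permutation p-values for low within-cluster response entropy.

    Response labels are resampled without replacement (permuted) across all
    subjects ``n_sims`` times; for each covariate cluster, the p-value is the
    smoothed fraction (r + 1) / (n_sims + 1) of simulated within-cluster
    entropies at or below the observed one (one-sided: low entropy is the
    significant direction).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    labels = np.asarray(resp_labels)
    if labels.size != cov_comp.n:
        raise ValueError("labels must align with the covariate composition")
    rng = np.random.default_rng(rng_seed)

    _, inv = np.unique(labels, return_inverse=True)
    n_levels = int(inv.max()) + 1
    member_idx = {k: cov_comp.members(k) for k in cov_comp.clusters}
    observed = {
        k: _entropy_from_counts(np.bincount(inv[idx], minlength=n_levels))
        for k, idx in member_idx.items()
    }
    # one independent permutation of the label vector per simulation
    perms = rng.permuted(np.tile(inv, (n_sims, 1)), axis=1)
    out = {}
    for k, idx in member_idx.items():
        sub = perms[:, idx]
        counts = (sub[:, :, None] == np.arange(n_levels)).sum(axis=1)
        p = counts / counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        r = int((h <= observed[k] + 1e-12).sum())
        out[k] = (r + 1) / (n_sims + 1)
    return out


def majority_error_rate(link: FlowLink, rule: str = "majority") -> tuple[dict, float]:
    """Per-cluster and size-weighted overall misclassification rates.

    majority rule: cluster error = 1 - (majority label share).
    randomized rule: cluster error = 1 - sum_l q_l^2 over within-cluster
    response label shares q_l (the chance a label-proportional random guess
    misses).
    """
    if rule not in ("majority", "randomized"):
        raise ValueError("rule must be 'majority' or 'randomized'")
    resp = link.response_comp.labels
    cov = link.covariate_comp
    per = {}
    for k in cov.clusters:
        members = cov.members(k)
        _, counts = np.unique(resp[members], return_counts=True)
        q = counts / counts.sum()
        per[k] = 1.0 - float(q.max()) if rule == "majority" else \
            1.0 - float((q ** 2).sum())
    p = cov.sizes / cov.n
    overall = float(sum(pk * per[k] for pk, k in zip(p, cov.clusters)))
    return per, overall


def serial_error_rate(flow: InformationFlow) -> float:
    """Error of the combined weighted-majority prediction across the serial links.

    Every subject receives, from each link, the majority response label of
    its covariate cluster; votes are averaged with the flow's
    inverse-entropy weights and the subject is assigned the label with the
    highest total weight.  Returns the fraction of subjects whose combined
    prediction differs from their response label.
    """
    resp = flow.links[0].response_comp.labels
    n = resp.size
    weights = flow.weights
    classes = np.unique(resp)
    votes = np.zeros((n, classes.size))
    class_idx = {c: i for i, c in enumerate(classes)}
    for w, link in zip(weights, flow.links):
        if link.response_comp.n != n:
            raise ValueError("links must share the same subjects")
        for k in link.covariate_comp.clusters:
            members = link.covariate_comp.members(k)
            votes[members, class_idx[link.majority_labels[k]]] += w
    predicted = classes[np.argmax(votes, axis=1)]
    err = float(np.mean(predicted != resp))
    flow.serial_error = err
    return err


@dataclass
class FlowConfig:
    """Parameters of the end-to-end information-flow pipeline."""

    renormalize: RenormalizeConfig = field(default_factory=RenormalizeConfig)
    dcg: DCGConfig = field(default_factory=DCGConfig)
    dm_max_iter: int = 3
    level_rule: str = "longest_plateau"
    n_sims: int = 1000
    epsilon: float = 1e-6
    alpha: float = 0.05


@dataclass
class FlowResult:
    """All artifacts of one end-to-end run."""

    response_coded: CodedMatrix
    covariate_coded: CodedMatrix
    response_groups: list[list[str]]
    covariate_groups: list[list[str]]
    response_feature_tree: DCGTree | None
    covariate_feature_tree: DCGTree | None
    response_geometries: dict
    covariate_geometries: dict
    flows: list[InformationFlow]

    def to_dict(self) -> dict:
        return {
            "response_groups": self.response_groups,
            "covariate_groups": self.covariate_groups,
            "flows": [f.to_dict() for f in self.flows],
        }


def _feature_groups(coded: CodedMatrix, cfg: FlowConfig, seed) -> tuple:
    """Synergistic feature groups from the DCG tree on the entropy matrix."""
    names = coded.feature_names
    if len(names) < 2:
        return [names], None
    xi = entropy_matrix(coded)
    D = DistanceMatrix.from_entropy_matrix(xi)
    if D.values[np.triu_indices(D.n, k=1)].max() <= 0:
        return [names], None
    tree = build_dcg_tree(D, cfg.dcg, seed)
    comp = tree.best_level(cfg.level_rule).composition
    groups = [
        [names[i] for i in np.flatnonzero(comp.labels == u)]
        for u in np.unique(comp.labels)
    ]
    return groups, tree


def build_information_flow(
    resp_coded: CodedMatrix,
    cov_coded: CodedMatrix,
    config: FlowConfig | None = None,
    rng_seed: int | None = None,
) -> FlowResult:
    """Discover and confirm information flows between two coded matrices.

    Pipeline: (1) entropy matrices on both sides -> DCG trees on features ->
    synergistic feature groups; (2) Data Mechanics per group -> row-marginal
    subject composition per group; (3) every response-group composition is
    paired with every covariate-group composition into a FlowLink with
    resampling p-values; (4) per response group, links are assembled into a
    serial InformationFlow ordered by ascending overall entropy, with its
    combined weighted-majority error rate.

    Both matrices must carry the same subjects in the same order.  Inputs
    are assumed already re-normalized; use :func:`renormalize_matrix` (or
    :func:`build_information_flow_raw`) for raw data.
    """
    cfg = config or FlowConfig()
    if resp_coded.subject_ids != cov_coded.subject_ids:
        raise ValueError("response and covariate matrices must share subjects "
                         "in identical order")
    ss = np.random.SeedSequence(rng_seed)

    def _seed(child) -> int:
        return int(child.generate_state(1)[0] % (2**31 - 1))

    children = iter(ss.spawn(1024))

    resp_groups, resp_tree = _feature_groups(resp_coded, cfg, _seed(next(children)))
    cov_groups, cov_tree = _feature_groups(cov_coded, cfg, _seed(next(children)))

    def _subject_comp(coded: CodedMatrix, group: list[str], seed) -> tuple:
        sub = coded.subset(group)
        if len(group) == 1:
            # single feature: its codes are the composition, no DM needed
            comp = ClusteringComposition(
                sub.codes[group[0]].to_numpy(), sub.subject_ids
            )
            return comp, None
        geom = run_data_mechanics(
            sub, max_iter=cfg.dm_max_iter, level_rule=cfg.level_rule,
            rng_seed=seed, dcg_config=cfg.dcg,
        )
        return geom.row_comp, geom

    resp_geoms, resp_comps = {}, {}
    for gi, group in enumerate(resp_groups):
        comp, geom = _subject_comp(resp_coded, group, _seed(next(children)))
        resp_comps[gi] = comp
        resp_geoms[gi] = geom
    cov_geoms, cov_comps = {}, {}
    for gi, group in enumerate(cov_groups):
        comp, geom = _subject_comp(cov_coded, group, _seed(next(children)))
        cov_comps[gi] = comp
        cov_geoms[gi] = geom

    flows = []
    for ri, rgroup in enumerate(resp_groups):
        links = []
        for ci, cgroup in enumerate(cov_groups):
            link = flow_entropy(
                resp_comps[ri], cov_comps[ci], name=f"covariate_group_{ci}"
            )
            link.pvalues = resampling_pvalues(
                resp_comps[ri].labels, cov_comps[ci],
                n_sims=cfg.n_sims, rng_seed=_seed(next(children)),
            )
            links.append(link)
        flow = InformationFlow(rgroup, links, epsilon=cfg.epsilon)
        serial_error_rate(flow)
        flows.append(flow)

    return FlowResult(
        response_coded=resp_coded,
        covariate_coded=cov_coded,
        response_groups=resp_groups,
        covariate_groups=cov_groups,
        response_feature_tree=resp_tree,
        covariate_feature_tree=cov_tree,
        response_geometries=resp_geoms,
        covariate_geometries=cov_geoms,
        flows=flows,
    )


def build_information_flow_raw(
    resp_raw,
    cov_raw,
    config: FlowConfig | None = None,
    rng_seed: int | None = None,
) -> FlowResult:
    """Convenience wrapper: re-normalize both raw matrices, then build flows."""
    cfg = config or FlowConfig()
    resp_coded, _ = renormalize_matrix(resp_raw, cfg.renormalize)
    cov_coded, _ = renormalize_matrix(cov_raw, cfg.renormalize)
    return build_information_flow(resp_coded, cov_coded, cfg, rng_seed)
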