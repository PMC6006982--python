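"""Data Cloud Geometry: ultrametric clustering from regulated random walks.

A distance matrix (for feature grouping, the mutual conditional-entropy
matrix; for subjects, Euclidean distances on coded rows) is scanned over a
geometric grid of temperatures T.  At each temperature the distances are
turned into a similarity matrix s_ij = exp(-d_ij / T), row-normalized into
a Markov transition matrix, and explored by an ensemble of *regulated*
random walks: a walk removes a node once its cumulative visit count passes
a threshold, and unusually long recurrence times between removals (spikes)
mark the walk entering a new region of the data cloud.  Nodes removed
between consecutive spikes share a cluster; averaging the co-cluster
indicator over the ensemble yields a cluster-sharing probability matrix
En whose number of significantly non-zero eigenvalues estimates the
cluster count N(T) at that scale.  Plateaus of N(T) across the temperature
grid are the data's natural scales; one clustering composition per plateau,
nested coarse to fine, is synthesized into an ultrametric tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .entropy import ClusteringComposition

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix of pairwise distances with named items."""

    item_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_names)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match item_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if self.values.min() < -1e-12:
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.item_names)

    @classmethod
    def from_entropy_matrix(cls, xi) -> "DistanceMatrix":
        return cls(list(xi.feature_names), xi.values)


@dataclass
class WalkTrajectory:
    """One regulated walk: removal order, recurrence times and spike flags."""

    removal_order: np.ndarray
    recurrence_times: np.ndarray
    spike_flags: np.ndarray

    def cluster_labels(self, n_items: int) -> np.ndarray:
        """Cluster index per item: nodes removed between spikes share a cluster."""
        labels = np.empty(n_items, dtype=int)
        labels[self.removal_order] = np.cumsum(self.spike_flags)
        return labels


@dataclass
class SharingMatrix:
    """Ensemble co-cluster frequencies: symmetric, unit diagonal, entries in [0,1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("sharing matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("sharing frequencies must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("sharing matrix must have unit diagonal")


@dataclass
class DCGLevel:
    """One tree level: a temperature and its clustering composition."""

    temperature: float
    composition: ClusteringComposition
    plateau_length: int = 1

    @property
    def n_clusters(self) -> int:
        return self.composition.n_clusters


@dataclass
class DCGConfig:
    """Tunable parameters of the DCG tree construction.

    visit_threshold
        A node is removed once its cumulative visit count exceeds this.
    n_trajectories
        Ensemble size per temperature.
    spike_factor
        A removal whose recurrence time exceeds spike_factor x the running
        median of recurrence times is flagged a spike.
    n_temperatures, q_low, q_high, t_lo_scale
        Geometric temperature grid with this many steps spanning
        t_lo_scale x the q_low-th percentile up to the q_high-th percentile
        of the positive distances.  The cold end sits below the typical
        distance because similarity contrast is exponential in d/T: walks
        only become confined to tight regions once T is a fraction of the
        distances to be resolved.
    min_run
        Minimum length of a constant run of N(T) to count as a plateau.
    eig_floor
        An eigenvalue below eig_floor x the top eigenvalue is never
        "significantly non-zero".
    """

    visit_threshold: int = 5
    n_trajectories: int = 100
    spike_factor: float = 5.0
    n_temperatures: int = 25
    q_low: float = 5.0
    q_high: float = 95.0
    t_lo_scale: float = 0.2
    min_run: int = 2
    eig_floor: float = 0.01


def similarity_from_distance(D: DistanceMatrix | np.ndarray, T: float) -> np.ndarray:
    """s_ij = exp(-d_ij / T); unit diagonal. T must be positive."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    return np.exp(-d / T)


def transition_from_similarity(S: np.ndarray) -> np.ndarray:
    """Row-normalize a nonnegative similarity matrix into a transition matrix."""
    S = np.asarray(S, dtype=float)
    if S.min() < 0:
        raise ValueError("similarities must be nonnegative")
    sums = S.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("isolated item: zero row sum")
    return S / sums[:, None]


@njit(cache=True)
def _walk_batch(P, threshold, n_traj, seed):  # pragma: no cover - compiled
    """Run n_traj regulated walks on transition matrix P.

    Returns (orders, recs): per trajectory, the node removal order and the
    number of arrivals between successive removals.
    """
    n = P.shape[0]
    orders = np.empty((n_traj, n), np.int64)
    recs = np.empty((n_traj, n), np.int64)
    np.random.seed(seed)
    for t in range(n_traj):
        active = np.ones(n, np.bool_)
        # the walk moves between distinct nodes: self-stays neither explore
        # nor count as visits, so rowsums exclude the diagonal
        rowsum = np.empty(n)
        for i in range(n):
            rowsum[i] = P[i].sum() - P[i, i]
        visits = np.zeros(n, np.int64)
        n_active = n
        cur = np.random.randint(0, n)
        visits[cur] = 1
        steps = 1
        k = 0
        while True:
            if visits[cur] > threshold:
                orders[t, k] = cur
                recs[t, k] = steps
                k += 1
                active[cur] = False
                n_active -= 1
                for i in range(n):
                    rowsum[i] -= P[i, cur]
                if n_active == 0:
                    break
                # continue from the removed node: one step along its own
                # transition row restricted to survivors, so the walk keeps
                # its locality in the data cloud
                rem_sum = 0.0
                for j in range(n):
                    if active[j] and j != cur:
                        rem_sum += P[cur, j]
                if rem_sum > 0.0:
                    u = np.random.random() * rem_sum
                    acc = 0.0
                    nxt = -1
                    for j in range(n):
                        if active[j]:
                            acc += P[cur, j]
                            if acc >= u:
                                nxt = j
                                break
                    if nxt == -1:
                        for j in range(n - 1, -1, -1):
                            if active[j]:
                                nxt = j
                                break
                    cur = nxt
                else:
                    # similarities underflowed: restart anywhere surviving
                    r = np.random.randint(0, n_active)
                    c = -1
                    for j in range(n):
                        if active[j]:
                            c += 1
                            if c == r:
                                cur = j
                                break
                visits[cur] += 1
                steps = 1
                continue
            # one Markov step to a distinct surviving node
            nxt = -1
            if rowsum[cur] > 0.0:
                u = np.random.random() * rowsum[cur]
                acc = 0.0
                for j in range(n):
                    if active[j] and j != cur:
                        acc += P[cur, j]
                        if acc >= u:
                            nxt = j
                            break
            if nxt == -1:
                # underflowed neighborhood: uniform jump among survivors
                r = np.random.randint(0, n_active)
                c = -1
                for j in range(n):
                    if active[j]:
                        c += 1
                        if c == r:
                            nxt = j
                            break
            cur = nxt
            visits[cur] += 1
            steps += 1
    return orders, recs


def _detect_spikes(recurrence: np.ndarray, spike_factor: float) -> np.ndarray:
    """Flag removals whose recurrence time exceeds spike_factor x running median."""
    n = recurrence.size
    flags = np.zeros(n, dtype=bool)
    for i in range(1, n):
        med = float(np.median(recurrence[:i]))
        if med > 0 and recurrence[i] > spike_factor * med:
            flags[i] = True
    return flags


def run_regulated_walks(
    P: np.ndarray,
    visit_threshold: int = 5,
    n_trajectories: int = 100,
    spike_factor: float = 5.0,
    rng_seed: int | None = None,
) -> tuple[list[WalkTrajectory], SharingMatrix]:
    """Ensemble of regulated random walks on a row-stochastic matrix P.

    Each walk starts at a uniformly random node, removes a node when its
    cumulative visit count exceeds ``visit_threshold`` (renormalizing the
    transition probabilities over survivors), and flags removals with
    unusually long recurrence times as spikes.  Nodes removed between
    consecutive spikes share a cluster; the sharing matrix is the ensemble
    mean of the co-cluster indicator.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    if n == 1:
        traj = WalkTrajectory(np.array([0]), np.array([1]), np.array([False]))
        return [traj] * n_trajectories, SharingMatrix(np.ones((1, 1)))
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P must be row-stochastic")
    seed = int(np.random.SeedSequence(rng_seed).generate_state(1)[0] % (2**31 - 1))
    orders, recs = _walk_batch(P, int(visit_threshold), int(n_trajectories), seed)
    trajectories = []
    co = np.zeros((n, n))
    for t in range(n_trajectories):
        flags = _detect_spikes(recs[t], spike_factor)
        traj = WalkTrajectory(orders[t], recs[t], flags)
        trajectories.append(traj)
        labels = traj.cluster_labels(n)
        co += labels[:, None] == labels[None, :]
    co /= n_trajectories
    np.fill_diagonal(co, 1.0)
    return trajectories, SharingMatrix(co)


def count_clusters(En: SharingMatrix | np.ndarray, eig_floor: float = 0.01) -> int:
    """Number of clusters = eigenvalue count before the largest relative gap.

    Eigenvalues of the sharing matrix are sorted descending; N is the index
    i maximizing (lambda_i - lambda_{i+1}) / lambda_i among indices whose
    eigenvalue is at least ``eig_floor`` times the top eigenvalue.
    """
    vals = En.values if isinstance(En, SharingMatrix) else np.asarray(En, dtype=float)
    n = vals.shape[0]
    if n == 1:
        return 1
    lam = np.linalg.eigvalsh(vals)[::-1]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        return 1
    best_i, best_gap = 1, -1.0
    for i in range(1, n):
        if lam[i - 1] < eig_floor * lam[0] or lam[i - 1] <= 0:
            break
        gap = (lam[i - 1] - lam[i]) / lam[i - 1]
        if gap > best_gap:
            best_i, best_gap = i, gap
    return best_i


def composition_at(
    En: SharingMatrix | np.ndarray, N: int, items: list[str] | None = None
) -> ClusteringComposition:
    """Average-linkage hierarchical clustering on 1 - En, cut at N clusters."""
    vals = En.values if isinstance(En, SharingMatrix) else np.asarray(En, dtype=float)
    n = vals.shape[0]
    if not 1 <= N <= n:
        raise ValueError("N must lie in [1, n]")
    if n == 1 or N == 1:
        return ClusteringComposition(np.zeros(n, dtype=int), items)
    dist = np.clip(1.0 - vals, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=N, criterion="maxclust")
    return ClusteringComposition(labels.astype(int), items)


@dataclass
class DCGTree:
    """Multi-level ultrametric clustering tree.

    Levels are ordered coarse to fine (cluster count non-decreasing,
    temperature strictly decreasing) and hierarchically nested, so the
    induced cophenetic distance is exactly ultrametric.
    """

    item_names: list[str]
    levels: list[DCGLevel]
    n_trace: list[tuple[float, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.item_names)

    def cophenetic_matrix(self) -> np.ndarray:
        """d(x, y) = temperature of the finest level where x and y co-cluster."""
        n = self.n
        root_t = self.levels[0].temperature
        coph = np.full((n, n), root_t)
        for level in self.levels:  # coarse -> fine overwrites with smaller T
            lab = level.composition.labels
            same = lab[:, None] == lab[None, :]
            coph[same] = level.temperature
        np.fill_diagonal(coph, 0.0)
        return coph

    def level_with_n_clusters(self, k: int) -> DCGLevel | None:
        for level in self.levels:
            if level.n_clusters == k:
                return level
        return None

    def best_level(self, rule: str = "longest_plateau") -> DCGLevel:
        """Select a working level; default: the longest-plateau non-root level."""
        if rule != "longest_plateau":
            raise ValueError(f"unknown level rule: {rule!r}")
        candidates = [lv for lv in self.levels if lv.n_clusters > 1]
        if not candidates:
            return self.levels[0]
        return max(candidates, key=lambda lv: lv.plateau_length)

    def to_dict(self) -> dict:
        return {
            "item_names": self.item_names,
            "levels": [
                {
                    "temperature": lv.temperature,
                    "n_clusters": lv.n_clusters,
                    "plateau_length": lv.plateau_length,
                    "labels": lv.composition.labels.tolist(),
                }
                for lv in self.levels
            ],
            "n_trace": [[t, n] for t, n in self.n_trace],
        }

    def to_newick(self) -> str:
        """Newick string with plateau temperatures as node heights.

        An internal node sits at the temperature of the level where its
        members first split; leaves sit at height 0; every edge length is
        the height difference between parent and child.
        """

        def node(members: np.ndarray, level_idx: int, parent_h: float) -> str:
            # advance to the next level that actually splits these members
            li = level_idx
            while li < len(self.levels):
                labs = self.levels[li].composition.labels[members]
                if len(np.unique(labs)) > 1:
                    break
                li += 1
            if li >= len(self.levels):
                if members.size == 1:
                    return f"{self.item_names[members[0]]}:{parent_h:.10g}"
                leaves = ",".join(f"{self.item_names[i]}:0" for i in members)
                return f"({leaves}):{parent_h:.10g}"
            t = self.levels[li].temperature
            labs = self.levels[li].composition.labels[members]
            parts = [
                node(members[labs == u], li + 1, t) for u in np.unique(labs)
            ]
            return "(" + ",".join(parts) + f"):{max(parent_h - t, 0.0):.10g}"

        all_members = np.arange(self.n)
        root_h = self.levels[0].temperature if self.levels else 1.0
        return node(all_members, 1, root_h) + ";"


def _constant_runs(ns: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of equal values: list of (start, stop) half-open index ranges."""
    runs = []
    start = 0
    for i in range(1, len(ns) + 1):
        if i == len(ns) or ns[i] != ns[start]:
            runs.append((start, i))
            start = i
    return runs


def _repair_nesting(levels: list[DCGLevel]) -> None:
    """Force coarse-to-fine nesting by reassigning fine clusters wholesale.

    Working from the finest level upward, every cluster of the finer level is
    placed entirely inside the coarse cluster holding the majority of its
    members; ties break toward the larger coarse cluster, then the smaller
    label.
    """
    for li in range(len(levels) - 2, -1, -1):
        coarse = levels[li].composition.labels
        fine = levels[li + 1].composition.labels
        coarse_sizes = {u: int((coarse == u).sum()) for u in np.unique(coarse)}
        new_coarse = coarse.copy()
        for u in np.unique(fine):
            members = np.flatnonzero(fine == u)
            labs, counts = np.unique(coarse[members], return_counts=True)
            best = max(
                zip(labs, counts),
                key=lambda lc: (lc[1], coarse_sizes[lc[0]], -_label_key(lc[0])),
            )[0]
            new_coarse[members] = best
        levels[li] = DCGLevel(
            levels[li].temperature,
            ClusteringComposition(new_coarse, levels[li].composition.items),
            levels[li].plateau_length,
        )


def _label_key(label) -> float:
    try:
        return float(label)
    except (TypeError, ValueError):
        return float(hash(label) % 10**6)


def build_dcg_tree(
    D: DistanceMatrix,
    config: DCGConfig | None = None,
    rng_seed: int | None = None,
) -> DCGTree:
    """Scan temperatures, find plateaus of N(T), synthesize the ultrametric tree.

    A geometric grid of temperatures spans the 5th to 95th percentile of the
    positive distances.  For each temperature the cluster count N(T) and
    composition are computed from the walk ensemble's sharing matrix; maximal
    constant runs of N(T) of length >= ``min_run`` are plateaus, each
    contributing one tree level at its middle temperature.  Levels are
    deduplicated per cluster count (longest plateau wins), completed with a
    one-cluster root, nesting-repaired coarse to fine, and given strictly
    decreasing temperatures so the cophenetic matrix is exactly ultrametric.
    """
    cfg = config or DCGConfig()
    n = D.n
    items = list(D.item_names)
    if n < 2:
        raise ValueError("need at least 2 items")

    pos = D.values[np.triu_indices(n, k=1)]
    pos = pos[pos > 0]
    if pos.size == 0:
        logger.warning("degenerate distance matrix (all zero); single-level tree")
        root = DCGLevel(1.0, ClusteringComposition(np.zeros(n, dtype=int), items), 1)
        return DCGTree(items, [root])

    t_lo = float(np.percentile(pos, cfg.q_low)) * cfg.t_lo_scale
    t_hi = float(np.percentile(pos, cfg.q_high))
    if t_lo <= 0:
        t_lo = float(pos.min()) * cfg.t_lo_scale
    if t_hi <= t_lo:
        grid = np.array([t_lo])
    else:
        grid = np.geomspace(t_lo, t_hi, cfg.n_temperatures)

    ss = np.random.SeedSequence(rng_seed)
    child_seeds = ss.spawn(len(grid))

    ns: list[int] = []
    comps: list[ClusteringComposition] = []
    for T, child in zip(grid, child_seeds):
        S = similarity_from_distance(D, float(T))
        P = transition_from_similarity(S)
        _, En = run_regulated_walks(
            P,
            visit_threshold=cfg.visit_threshold,
            n_trajectories=cfg.n_trajectories,
            spike_factor=cfg.spike_factor,
            rng_seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        N = count_clusters(En, cfg.eig_floor)
        ns.append(N)
        comps.append(composition_at(En, N, items))

    n_trace = [(float(t), k) for t, k in zip(grid, ns)]

    # plateau detection: middle point of each constant run of N(T)
    candidates: dict[int, DCGLevel] = {}
    min_run = cfg.min_run if len(grid) > 1 else 1
    for start, stop in _constant_runs(ns):
        length = stop - start
        if length < min_run:
            continue
        mid = (start + stop - 1) // 2
        k = ns[mid]
        if k not in candidates or candidates[k].plateau_length < length:
            candidates[k] = DCGLevel(float(grid[mid]), comps[mid], length)

    if not candidates:
        # no plateau long enough: fall back to the most frequent N(T)
        k = int(np.bincount(ns).argmax())
        mid = ns.index(k)
        candidates[k] = DCGLevel(float(grid[mid]), comps[mid], 1)

    if 1 not in candidates:
        root_t = float(grid.max()) * 1.5
        candidates[1] = DCGLevel(
            root_t, ClusteringComposition(np.zeros(n, dtype=int), items), 0
        )

    levels = [candidates[k] for k in sorted(candidates)]
    _repair_nesting(levels)

    # drop levels made redundant by the repair, keep the coarsest copy
    deduped: list[DCGLevel] = []
    for lv in levels:
        if deduped and lv.composition.same_partition(deduped[-1].composition):
            continue
        deduped.append(lv)

    # strictly decreasing temperatures coarse -> fine (ultrametric heights)
    for i in range(1, len(deduped)):
        cap = deduped[i - 1].temperature * (1 - 1e-9)
        if deduped[i].temperature >= cap:
            deduped[i] = DCGLevel(
                cap * 0.999, deduped[i].composition, deduped[i].plateau_length
            )

    return DCGTree(items, deduped, n_trace)


def euclidean_distance_matrix(X: np.ndarray, names: list[str]) -> DistanceMatrix:
    """Plain pairwise Euclidean distances between the rows of X."""
    from scipy.spatial.distance import pdist

    d = squareform(pdist(np.asarray(X, dtype=float)))
    return DistanceMatrix(names, d)
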