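"""Data Mechanics: alternating row/column ultrametric clustering of a coded matrix.

The algorithm iterates DCG tree building on the two axes of a coded matrix.
Starting from plain Euclidean distances between rows, each subsequent axis
uses distances *augmented* by the current clustering on the other axis:
every vector is extended with the mean code over the members of each
opposite-axis cluster, so that the geometry discovered on one axis informs
the next clustering of the other.  Iteration stops when both selected
compositions stop changing (typically within two or three rounds).  The
result — the matrix framed by its two marginal ultrametric trees — is the
*coupling geometry*: multiscale blocks that are as internally uniform (low
within-block total variation, or "energy") as the data allow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dcg import DCGConfig, DCGTree, DistanceMatrix, build_dcg_tree
from .entropy import ClusteringComposition

logger = logging.getLogger(__name__)


@dataclass
class CouplingGeometry:
    """A coded matrix framed by marginal row and column ultrametric trees."""

    matrix: pd.DataFrame
    row_tree: DCGTree
    col_tree: DCGTree
    row_comp: ClusteringComposition
    col_comp: ClusteringComposition
    energy_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def row_order(self) -> np.ndarray:
        return _leaf_order(self.row_tree)

    @property
    def col_order(self) -> np.ndarray:
        return _leaf_order(self.col_tree)

    def permuted(self) -> pd.DataFrame:
        """The matrix re-ordered by the two trees' leaf orders."""
        return self.matrix.iloc[self.row_order, self.col_order]

    def energy(self) -> float:
        return matrix_energy(self.matrix.to_numpy(), self.row_comp, self.col_comp)

    def to_dict(self) -> dict:
        return {
            "row_tree": self.row_tree.to_dict(),
            "col_tree": self.col_tree.to_dict(),
            "row_labels": self.row_comp.labels.tolist(),
            "col_labels": self.col_comp.labels.tolist(),
            "row_order": self.row_order.tolist(),
            "col_order": self.col_order.tolist(),
            "energy_trace": list(self.energy_trace),
            "n_iterations": self.n_iterations,
        }


def _leaf_order(tree: DCGTree) -> np.ndarray:
    """Leaf permutation sorting items lexicographically through the tree levels."""
    if not tree.levels:
        return np.arange(tree.n)
    keys = [lv.composition.labels for lv in tree.levels]
    keys.append(np.arange(tree.n))
    return np.lexsort(tuple(reversed(keys)))


def augmented_distance(
    matrix: np.ndarray | pd.DataFrame,
    other_axis_comp: ClusteringComposition,
    axis: str,
    names: list[str] | None = None,
) -> DistanceMatrix:
    """Euclidean distances on vectors extended with opposite-axis cluster means.

    For ``axis="col"`` each column (length n) is extended with N* extra
    coordinates — its mean over the member rows of each cluster of
    ``other_axis_comp`` (a composition of the rows) — and pairwise Euclidean
    distance is taken on the (n + N*)-dimensional vectors; symmetrically for
    ``axis="row"``.  The extra coordinates are unweighted.
    """
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
        row_names = [str(i) for i in matrix.index]
        col_names = [str(c) for c in matrix.columns]
    else:
        X = np.asarray(matrix, dtype=float)
        row_names = [str(i) for i in range(X.shape[0])]
        col_names = [str(j) for j in range(X.shape[1])]

    if axis == "col":
        vectors = X.T
        item_names = names or col_names
    elif axis == "row":
        vectors = X
        item_names = names or row_names
    else:
        raise ValueError("axis must be 'row' or 'col'")

    labels = other_axis_comp.labels
    if labels.size != vectors.shape[1]:
        raise ValueError("composition must be defined on the opposite axis")
    means = np.column_stack(
        [vectors[:, labels == u].mean(axis=1) for u in np.unique(labels)]
    )
    extended = np.hstack([vectors, means])
    d = squareform(pdist(extended))
    return DistanceMatrix(item_names, d)


def matrix_energy(
    values: np.ndarray,
    row_comp: ClusteringComposition,
    col_comp: ClusteringComposition,
) -> float:
    """Within-block total variation: sum over blocks of squared deviations.

    For every (row cluster x column cluster) block, sums (x - block mean)^2
    over the block's entries.  Zero for perfectly uniform blocks; for the
    trivial single-block partition this is the overall matrix variance times
    the number of entries.
    """
    X = np.asarray(values, dtype=float)
    total = 0.0
    for r in np.unique(row_comp.labels):
        rows = row_comp.labels == r
        for c in np.unique(col_comp.labels):
            block = X[np.ix_(rows, col_comp.labels == c)]
            if block.size:
                total += float(((block - block.mean()) ** 2).sum())
    return total


def run_data_mechanics(
    coded,
    max_iter: int = 3,
    level_rule: str = "longest_plateau",
    rng_seed: int | None = None,
    dcg_config: DCGConfig | None = None,
) -> CouplingGeometry:
    """Alternate DCG clustering on rows and columns until both stabilize.

    Iteration 0 builds the row tree from plain Euclidean distances between
    rows.  Each round then rebuilds the column tree from row-cluster-mean
    augmented distances and the row tree from column-cluster-mean augmented
    distances, selecting a working level on each tree by ``level_rule``.
    Stops as soon as both selected compositions repeat, or after
    ``max_iter`` rounds.  The energy trace starts at the single-block
    baseline and records the within-block energy after each round.
    """
    frame = coded.codes if hasattr(coded, "codes") else pd.DataFrame(coded)
    X = frame.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_names = [str(i) for i in frame.index]
    col_names = [str(c) for c in frame.columns]

    cfg = dcg_config or DCGConfig()
    ss = np.random.SeedSequence(rng_seed)
    seeds = iter(ss.spawn(2 * max_iter + 1))

    def _seed(child) -> int:
        return int(child.generate_state(1)[0] % (2**31 - 1))

    trivial_rows = ClusteringComposition(np.zeros(n, dtype=int), row_names)
    trivial_cols = ClusteringComposition(np.zeros(m, dtype=int), col_names)
    energy_trace = [matrix_energy(X, trivial_rows, trivial_cols)]

    row_D = DistanceMatrix(row_names, squareform(pdist(X)))
    row_tree = build_dcg_tree(row_D, cfg, _seed(next(seeds)))
    row_comp = _with_items(row_tree.best_level(level_rule).composition, row_names)
    col_tree = build_dcg_tree(
        augmented_distance(frame, row_comp, axis="col"), cfg, _seed(next(seeds))
    )
    col_comp = _with_items(col_tree.best_level(level_rule).composition, col_names)
    energy_trace.append(matrix_energy(X, row_comp, col_comp))

    n_iterations = 1
    for _ in range(1, max_iter):
        new_row_tree = build_dcg_tree(
            augmented_distance(frame, col_comp, axis="row"), cfg, _seed(next(seeds))
        )
        new_row_comp = _with_items(
            new_row_tree.best_level(level_rule).composition, row_names
        )
        new_col_tree = build_dcg_tree(
            augmented_distance(frame, new_row_comp, axis="col"), cfg,
            _seed(next(seeds)),
        )
        new_col_comp = _with_items(
            new_col_tree.best_level(level_rule).composition, col_names
        )
        stable = new_row_comp.same_partition(row_comp) and \
            new_col_comp.same_partition(col_comp)
        row_tree, row_comp = new_row_tree, new_row_comp
        col_tree, col_comp = new_col_tree, new_col_comp
        n_iterations += 1
        energy_trace.append(matrix_energy(X, row_comp, col_comp))
        if stable:
            break

    return CouplingGeometry(
        matrix=frame,
        row_tree=row_tree,
        col_tree=col_tree,
        row_comp=row_comp,
        col_comp=col_comp,
        energy_trace=energy_trace,
        n_iterations=n_iterations,
    )


def _with_items(comp: ClusteringComposition, items: list[str]) -> ClusteringComposition:
    return ClusteringComposition(comp.labels.copy(), items)
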