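"""Combinatorial information-theory kernel.

Entropies here are entropies of *clustering compositions*: a population of
N subjects divided into K clusters of sizes N_1..N_K has entropy
H = -sum_k p_k log p_k with p_k = N_k / N.  The association between two
compositions Y and X on the same subjects is measured by the mutual
conditional entropy

    E[Y <=> X] = 1/2 ( H(Y|X)/H(Y) + H(X|Y)/H(X) ),

a symmetric quantity in [0, 1]: it is 0 exactly when the two label vectors
correspond bijectively (perfect categorical correspondence) and approaches
1 when they are independent.  Natural log is the default base; the base
only rescales raw entropies and cancels in the normalized ratios.

Conventions: 0 log 0 = 0, and a ratio term with a zero marginal entropy
contributes 0 (a constant feature is perfectly predicted by anything).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClusteringComposition:
    """Per-subject cluster labels with derived sizes and proportions."""

    labels: np.ndarray
    items: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if self.items is not None and len(self.items) != self.labels.size:
            raise ValueError("items must align with labels")

    @classmethod
    def from_labels(cls, labels, items=None) -> "ClusteringComposition":
        return cls(np.asarray(labels), list(items) if items is not None else None)

    def _decompose(self):
        # unique labels, integer recoding and counts, computed once
        cached = getattr(self, "_cache", None)
        if cached is None:
            cached = np.unique(self.labels, return_inverse=True,
                               return_counts=True)
            object.__setattr__(self, "_cache", cached)
        return cached

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def clusters(self) -> np.ndarray:
        return self._decompose()[0]

    @property
    def indices(self) -> np.ndarray:
        """Labels recoded to 0..K-1 in cluster order."""
        return self._decompose()[1]

    @property
    def sizes(self) -> np.ndarray:
        return self._decompose()[2]

    @property
    def proportions(self) -> np.ndarray:
        return self.sizes / self.n

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, cluster) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def same_partition(self, other: "ClusteringComposition") -> bool:
        """True when the two label vectors induce the same partition."""
        if self.n != other.n:
            return False
        _, a = np.unique(self.labels, return_inverse=True)
        _, b = np.unique(other.labels, return_inverse=True)
        pairs = set(zip(a.tolist(), b.tolist()))
        return len({x for x, _ in pairs}) == len(pairs) == len({y for _, y in pairs})


@dataclass
class EntropyMatrix:
    """Symmetric m x m matrix of mutual conditional entropies between features."""

    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.feature_names)
        if self.values.shape != (m, m):
            raise ValueError("values must be square and match feature_names")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("entropy matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("entropy matrix must have zero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names,
                            columns=self.feature_names)


def _entropy_from_counts(counts: np.ndarray, base: float | None = None) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def uniform_uncertainty(n: int, base: float | None = 2) -> float:
    """A(N): the entropy of the uniform composition over N singletons (log N)."""
    if n < 1:
        raise ValueError("n must be positive")
    return float(np.log(n) / (np.log(base) if base is not None else 1.0))


def shannon_entropy(comp: ClusteringComposition, base: float | None = None) -> float:
    """H(X) = -sum_k p_k log p_k of a clustering composition."""
    return _entropy_from_counts(comp.sizes, base)


def _check_same_subjects(y: ClusteringComposition, x: ClusteringComposition) -> None:
    if y.n != x.n:
        raise ValueError("compositions are defined on different subject sets")
    if y.items is not None and x.items is not None and y.items != x.items:
        raise ValueError("compositions are defined on different subject sets")


def _joint_table(y: ClusteringComposition, x: ClusteringComposition) -> np.ndarray:
    """Contingency counts with x clusters as rows, y clusters as columns."""
    ky = len(y.clusters)
    kx = len(x.clusters)
    joint = np.bincount(x.indices * ky + y.indices, minlength=kx * ky)
    return joint.reshape(kx, ky)


def _row_entropies(table: np.ndarray, base: float | None = None) -> np.ndarray:
    totals = table.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, table / np.where(totals > 0, totals, 1), 0.0)
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if base is not None:
        h /= np.log(base)
    return h


def conditional_entropy_by_cluster(
    y: ClusteringComposition, x: ClusteringComposition, base: float | None = None
) -> dict:
    """H(Y | X=k) for every cluster k of x."""
    _check_same_subjects(y, x)
    h = _row_entropies(_joint_table(y, x), base)
    return dict(zip(x.clusters, h.tolist()))


def conditional_entropy(
    y: ClusteringComposition, x: ClusteringComposition, base: float | None = None
) -> float:
    """H(Y|X) = sum_k p_k H(Y | X=k): size-weighted within-cluster entropy of y."""
    _check_same_subjects(y, x)
    table = _joint_table(y, x)
    h = _row_entropies(table, base)
    return float((x.sizes / x.n) @ h)


def mutual_conditional_entropy(
    y: ClusteringComposition, x: ClusteringComposition
) -> float:
    """E[Y <=> X] = 1/2 (H(Y|X)/H(Y) + H(X|Y)/H(X)), in [0, 1].

    A term whose marginal entropy is zero contributes 0: a constant
    composition is perfectly predicted.
    """
    hy = shannon_entropy(y)
    hx = shannon_entropy(x)
    term_y = conditional_entropy(y, x) / hy if hy > 0 else 0.0
    term_x = conditional_entropy(x, y) / hx if hx > 0 else 0.0
    return 0.5 * (term_y + term_x)


def entropy_matrix(coded, roles: str | None = None) -> EntropyMatrix:
    """Pairwise mutual conditional entropies between the columns of a coded matrix.

    Each distinct code in a column is treated as one category.  ``coded`` may
    be a CodedMatrix or a plain DataFrame of integer codes; ``roles`` filters
    to features with that declared role ("response" or "covariate").
    """
    if hasattr(coded, "codes"):
        frame = coded.codes
        if roles is not None:
            keep = [s.name for s in coded.specs if s.role == roles]
            frame = frame[keep]
    else:
        frame = pd.DataFrame(coded)
    names = list(frame.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 features for an entropy matrix")
    comps = {}
    for name in names:
        col = frame[name].to_numpy()
        if len(np.unique(col)) == 1:
            logger.warning("feature %r is constant; zero-entropy convention applies",
                           name)
        comps[name] = ClusteringComposition.from_labels(col)
    m = len(names)
    xi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            xi[i, j] = xi[j, i] = mutual_conditional_entropy(
                comps[names[i]], comps[names[j]]
            )
    return EntropyMatrix(names, xi)
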