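"""Pearson-distance hierarchical clustering, module extraction and PCA.

Distances are d(i, j) = 1 - r(i, j), with r the Pearson product-moment
correlation, so perfectly co-expressed items sit at distance 0 and perfectly
anti-correlated items at distance 2. Trees are agglomerative with average
linkage (UPGMA); items are sorted lexicographically by id before linkage, so
the partition returned by :func:`cut` does not depend on input order.
A squared-Euclidean distance option is available for sample-level views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "ClusterTree",
    "ModuleAssignment",
    "pearson_r",
    "distance_matrix",
    "cluster",
    "cut",
    "pca_overview",
]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between named items."""

    item_ids: tuple[str, ...]
    d: np.ndarray
    metric: str = "pearson"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.item_ids)
        if d.shape != (n, n):
            raise ValueError("distance grid does not match item ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("self-distances must be zero")
        object.__setattr__(self, "d", d)

    def value(self, a: str, b: str) -> float:
        i, j = self.item_ids.index(a), self.item_ids.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.item_ids),
                            columns=list(self.item_ids))


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over named items.

    ``linkage`` is a scipy linkage matrix over ``item_ids`` (already in the
    tree's internal, lexicographically sorted order).
    """

    item_ids: tuple[str, ...]
    linkage: np.ndarray
    method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_history(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage,
                            columns=["left", "right", "height", "size"])


@dataclass(frozen=True)
class ModuleAssignment:
    """Partition of items into k modules labelled I, II, III, ..."""

    assignment: dict[str, str]
    k: int

    def members(self, label: str) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == label)

    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def as_sets(self) -> set[frozenset[str]]:
        """Label-free view of the partition (for comparing clusterings)."""
        return {frozenset(self.members(lab)) for lab in self.labels()}


def _roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[i] if i < len(numerals) else str(i + 1)


def distance_matrix(
    m: ExpressionMatrix,
    axis: Literal["genes", "samples"] = "genes",
    metric: Literal["pearson", "sqeuclidean"] = "pearson",
) -> DistanceMatrix:
    """Pairwise 1 - r (or squared-Euclidean) distances along genes or samples."""
    if axis == "genes":
        data = m.values.to_numpy(dtype=float)
        ids = tuple(m.values.index)
    elif axis == "samples":
        data = m.values.to_numpy(dtype=float).T
        ids = tuple(m.values.columns)
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    return distance_matrix_from_rows(data, ids, metric=metric)


def distance_matrix_from_rows(
    data: np.ndarray,
    ids: Sequence[str],
    metric: Literal["pearson", "sqeuclidean"] = "pearson",
) -> DistanceMatrix:
    data = np.asarray(data, dtype=float)
    if metric == "pearson":
        if data.shape[1] < 3:
            raise ValueError("need at least 3 observations per vector")
        sd = data.std(axis=1)
        if (sd == 0).any():
            bad = np.asarray(ids)[sd == 0][0]
            raise ValueError(f"zero-variance vector: {bad!r}")
        r = np.corrcoef(data)
        d = 1.0 - np.clip(r, -1.0, 1.0)
    elif metric == "sqeuclidean":
        diff = data[:, None, :] - data[None, :, :]
        d = (diff * diff).sum(axis=2)
    else:
        raise ValueError("metric must be 'pearson' or 'sqeuclidean'")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(ids), d, metric=metric)


def cluster(d: DistanceMatrix, method: str = "average") -> ClusterTree:
    """Agglomerative clustering of a distance matrix (UPGMA by default).

    Items are sorted by id before linkage so the merge history — and any cut
    of it — is invariant to the order items were supplied in.
    """
    order = np.argsort(np.asarray(d.item_ids))
    ids = tuple(np.asarray(d.item_ids)[order])
    grid = d.d[np.ix_(order, order)]
    z = sch.linkage(squareform(grid, checks=False), method=method)
    return ClusterTree(ids, z, method=method)


def cut(tree: ClusterTree, k: int) -> ModuleAssignment:
    """Cut the tree into exactly k modules by merge height.

    Modules are labelled I, II, III, ... in order of their lowest-id member.
    """
    n = len(tree.item_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = sch.cut_tree(tree.linkage, n_clusters=k).ravel()
    # stable relabelling: module of the alphabetically first item gets label I
    seen: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for item, raw in zip(tree.item_ids, flat):
        if raw not in seen:
            seen[raw] = _roman(len(seen))
        assignment[item] = seen[raw]
    return ModuleAssignment(assignment, k)


def pca_overview(m: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Per-sample principal-component scores of gene-centered expression.

    Returns a DataFrame (samples x components, columns PC1, PC2, ...) plus a
    ``variance_ratio`` attribute in ``DataFrame.attrs``; component variances
    are non-increasing.
    """
    n_samples = len(m.sample_ids)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_components > n_samples:
        raise ValueError("fewer samples than requested components")
    # samples are the observations; centering each gene is what PCA's
    # per-feature centering does on the samples x genes layout
    x = m.values.to_numpy(dtype=float).T
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    out = pd.DataFrame(scores, index=m.sample_ids,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.attrs["variance_ratio"] = pca.explained_variance_ratio_
    return out
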