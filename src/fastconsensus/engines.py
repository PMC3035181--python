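"""Clustering engines: Euclidean agglomerative hierarchies and Lloyd K-means.

The hierarchical engines (average / complete / single linkage) build one
merge tree per input; a k-group partition is extracted by undoing the last
k - 1 merges. Because the tree is built once and can be cut at every k, these
engines are what makes the loop-switched FC procedure fast. K-means variants
start either from a uniformly random partition (kmeans-r) or from the
k-cut of a hierarchical dendrogram (kmeans-a / kmeans-c / kmeans-s).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "pairwise_distances",
    "build_dendrogram",
    "cut_dendrogram",
    "cut_dendrogram_multi",
    "kmeans",
    "random_partition",
    "canonicalize_labels",
    "LINKAGE_OF",
]

#: linkage name used by scipy for each hierarchical engine token
LINKAGE_OF = {
    "hier-a": "average",
    "hier-c": "complete",
    "hier-s": "single",
    "kmeans-a": "average",
    "kmeans-c": "complete",
    "kmeans-s": "single",
}


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Square symmetric matrix of Euclidean distances between rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    return squareform(pdist(X, metric="euclidean"))


def build_dendrogram(dist: np.ndarray, method: str) -> np.ndarray:
    """Agglomerative merge tree for a square distance matrix.

    ``method`` is one of ``average``, ``complete``, ``single``. Returns the
    (n-1, 4) scipy linkage matrix; deterministic for a given input.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    condensed = squareform(np.asarray(dist, dtype=float), checks=False)
    return linkage(condensed, method=method)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel groups as 0..k-1 in order of first occurrence.

    The group containing the smallest item index gets id 0, and so on; every
    id in [0, k) occurs.
    """
    labels = np.asarray(labels)
    _, first_pos, inverse = np.unique(labels, return_index=True, return_inverse=True)
    # rank of each unique value by first occurrence
    order = np.empty(first_pos.size, dtype=int)
    order[np.argsort(first_pos)] = np.arange(first_pos.size)
    return order[inverse]


def cut_dendrogram(Z: np.ndarray, k: int) -> np.ndarray:
    """Partition into exactly k groups by undoing the last k-1 merges."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = cut_tree(Z, n_clusters=k).ravel()
    return canonicalize_labels(labels)


def cut_dendrogram_multi(Z: np.ndarray, ks: Sequence[int]) -> dict[int, np.ndarray]:
    """Cuts of one dendrogram at several k, harvested in a single pass."""
    n = Z.shape[0] + 1
    ks = list(ks)
    for k in ks:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
    cuts = cut_tree(Z, n_clusters=ks)
    return {k: canonicalize_labels(cuts[:, j]) for j, k in enumerate(ks)}


def random_partition(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labeling of n points into k groups, redrawn until every
    group is non-empty."""
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    while True:
        labels = rng.integers(0, k, size=n)
        if np.unique(labels).size == k:
            return labels


def kmeans(
    X: np.ndarray,
    k: int,
    init_labels: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd K-means from an explicit initial partition.

    The initial centroids are the group means of ``init_labels``; when no
    partition is given a uniformly random one is drawn from ``rng``. One
    initialization per call, at most ``max_iter`` sweeps, convergence when no
    assignment changes; an emptied cluster is repopulated with the point
    farthest from its centroid. Deterministic given the initial partition.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if init_labels is None:
        if rng is None:
            raise ValueError("either init_labels or rng must be provided")
        init_labels = random_partition(n, k, rng)
    init_labels = np.asarray(init_labels)
    if init_labels.shape != (n,):
        raise ValueError("init_labels must have one entry per point")
    centers = np.stack([X[init_labels == c].mean(axis=0) for c in range(k)])
    est = KMeans(
        n_clusters=k,
        init=centers,
        n_init=1,
        max_iter=max_iter,
        tol=0.0,
        algorithm="lloyd",
        random_state=0,
    )
    return canonicalize_labels(est.fit_predict(X))
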