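"""Synthetic benchmark generators with a known gold number of clusters.

Two families emulate the artificial expression benchmarks commonly used to
validate cluster-number estimators: well-separated multivariate Gaussian
clusters, and marker-block data in which each class over-expresses its own
disjoint block of features against a Gaussian background. Named presets
(``gaussian3``, ``gaussian5``, ``simulated6``) fix analogs of the classic
three-, five- and six-class artificial datasets with gold k of 3, 5 and 6;
``null`` provides a structureless negative control. The presets are analogs —
they preserve the gold k and the qualitative regime (high-dimensional
well-separated Gaussians; low-dimensional multi-cluster; marker blocks),
not any specific dataset's exact numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LabeledDataset",
    "gaussian_clusters",
    "marker_block_dataset",
    "null_dataset",
    "make_preset",
    "PRESETS",
]


@dataclass
class LabeledDataset:
    """An expression matrix together with its gold partition."""

    X: np.ndarray  # n items x d conditions
    true_labels: np.ndarray
    true_k: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return [f"item_{i}" for i in range(self.X.shape[0])]

    @property
    def condition_ids(self) -> list[str]:
        return [f"cond_{j}" for j in range(self.X.shape[1])]


def _class_means(k: int, n_dims: int, separation: float) -> np.ndarray:
    """Class means pairwise c-separated for c = ``separation``.

    Separation follows the standard c-separation convention for Gaussian
    mixtures: every pair of class means lies at Euclidean distance
    >= separation * sqrt(n_dims), i.e. ``separation`` is measured in units
    of the within-class RMS radius (sigma * sqrt(d) with sigma = 1). This
    keeps "separation 6" meaning the same degree of cluster separability in
    2 dimensions and in 200: with a fixed absolute distance, noise
    accumulating over dimensions would swamp any fixed gap.

    Placement: for k <= n_dims a scaled standard-basis simplex (all pairs
    exactly at the target distance); otherwise, for n_dims >= 2, a regular
    k-gon in the first two coordinates whose shortest chord equals the
    target; in one dimension, equally spaced points.
    """
    means = np.zeros((k, n_dims))
    if k == 1 or separation == 0:
        return means
    target = separation * np.sqrt(n_dims)
    if k <= n_dims:
        for c in range(k):
            means[c, c] = target / np.sqrt(2.0)
    elif n_dims >= 2:
        radius = target / (2.0 * np.sin(np.pi / k))
        angles = 2.0 * np.pi * np.arange(k) / k
        means[:, 0] = radius * np.cos(angles)
        means[:, 1] = radius * np.sin(angles)
    else:
        means[:, 0] = target * np.arange(k)
    return means


def gaussian_clusters(
    sizes: Sequence[int],
    n_dims: int,
    separation: float,
    rng: np.random.Generator,
) -> LabeledDataset:
    """Spherical unit-variance Gaussian classes with c-separated means.

    ``separation`` is the minimal inter-mean Euclidean distance in units of
    the within-class RMS radius sqrt(n_dims) (per-coordinate SD is 1), the
    c-separation convention for Gaussian mixtures; separation 0 collapses
    all classes onto one mean.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("every class size must be >= 1")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    k = len(sizes)
    means = _class_means(k, n_dims, separation)
    labels = np.repeat(np.arange(k), sizes)
    X = rng.standard_normal((sum(sizes), n_dims)) + means[labels]
    return LabeledDataset(X=X, true_labels=labels, true_k=k)


def marker_block_dataset(
    sizes: Sequence[int],
    n_features: int,
    markers_per_class: int,
    effect: float,
    rng: np.random.Generator,
) -> LabeledDataset:
    """Marker-block ("up pattern") expression data on a Gaussian background.

    Each class c over-expresses its own disjoint block of
    ``markers_per_class`` features by ``effect`` noise standard deviations;
    all other cells are standard Gaussian noise.
    """
    sizes = [int(s) for s in sizes]
    k = len(sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("every class size must be >= 1")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if k * markers_per_class > n_features:
        raise ValueError(
            f"marker blocks exceed feature count: {k} * {markers_per_class} > {n_features}"
        )
    labels = np.repeat(np.arange(k), sizes)
    X = rng.standard_normal((sum(sizes), n_features))
    for c in range(k):
        block = slice(c * markers_per_class, (c + 1) * markers_per_class)
        X[labels == c, block] += effect
    return LabeledDataset(X=X, true_labels=labels, true_k=k)


def null_dataset(n: int, n_dims: int, rng: np.random.Generator) -> LabeledDataset:
    """Structureless i.i.d. standard Gaussian matrix; gold k = 1."""
    if n < 3:
        raise ValueError("n must be >= 3")
    X = rng.standard_normal((int(n), int(n_dims)))
    return LabeledDataset(X=X, true_labels=np.zeros(n, dtype=int), true_k=1)


def make_preset(name: str, rng: np.random.Generator) -> LabeledDataset:
    """Named benchmark analogs with gold k of 3, 5, 6 (and the null control)."""
    if name == "gaussian3":
        return gaussian_clusters((20, 20, 20), n_dims=200, separation=6.0, rng=rng)
    if name == "gaussian5":
        return gaussian_clusters((80, 120, 100, 120, 80), n_dims=2, separation=6.0, rng=rng)
    if name == "simulated6":
        return marker_block_dataset(
            (8, 12, 10, 15, 5, 10), n_features=600, markers_per_class=50, effect=2.0, rng=rng
        )
    if name == "null":
        return null_dataset(60, 100, rng)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")


PRESETS = ("gaussian3", "gaussian5", "simulated6", "null")
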