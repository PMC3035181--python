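"""scikit-learn style estimator wrapping the Consensus / FC procedures."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .config import RunConfig
from .consensus import run_consensus, run_fc
from .curves import compute_curves, predict_k
from .engines import LINKAGE_OF, build_dendrogram, cut_dendrogram, kmeans, pairwise_distances
from .resampling import child_rng


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Stability-based estimation of the number of clusters by consensus.

    For every candidate k in ``[k_min, k_max]`` the data are repeatedly
    subsampled (``n_resamples`` draws of a ``subsample_fraction`` of the
    rows) and clustered; the consensus matrix records, for each item pair,
    the fraction of co-draws in which the pair co-clustered. The area A(k)
    under the empirical CDF of consensus entries and its proportional
    increase Δ(k) locate the number of clusters k* at which the clustering
    stabilizes (Δ plateau below ``tau``).

    Parameters
    ----------
    method : {"fc", "consensus"}, default="fc"
        ``"consensus"`` draws fresh resamples for every k (k-outer loop);
        ``"fc"`` is the loop-switched variant sharing one resample — and,
        for hierarchical engines, one dendrogram — across all k. The two
        produce statistically equivalent consensus matrices; FC is roughly
        (k_max - k_min + 1) times cheaper in dendrogram constructions.
    algorithm : str, default="hier-a"
        Clustering engine: ``hier-a``/``hier-c``/``hier-s`` (agglomerative,
        average/complete/single linkage, Euclidean distance) or
        ``kmeans-r``/``kmeans-a``/``kmeans-c``/``kmeans-s`` (Lloyd K-means
        from a random partition or from a hierarchical cut).
    n_resamples : int, default=250
        Number of resampling steps H.
    subsample_fraction : float, default=0.8
        Fraction p of rows drawn (without replacement) per resample.
    k_min, k_max : int, defaults 2 and 30
        Candidate range for the number of clusters; ``k_max`` must not
        exceed ``floor(p * n)``.
    tau : float, default=0.03
        Plateau threshold for the automatic k* rule.
    random_state : int or None, default=None
        Master seed; every resample derives a child stream from it.

    Attributes
    ----------
    k_star_ : int
        Predicted number of clusters.
    stabilized_ : bool
        Whether the Δ curve actually stabilized below ``tau`` (otherwise
        ``k_star_`` is the fallback ``k_max - 1``).
    flat_range_ : tuple or None
        Maximal contiguous k interval with Δ <= tau, surfacing interval
        ambiguity (e.g. "5 - 6" style predictions).
    consensus_matrices_ : dict[int, numpy.ndarray]
        Per-k consensus matrices (symmetric, entries in [0, 1]).
    areas_, deltas_ : dict[int, float]
        A(k) and Δ(k) series.
    cdf_curves_ : dict[int, CDFCurve]
        Per-k empirical CDF curves for visual inspection.
    labels_ : ndarray
        Clustering of the full data into ``k_star_`` groups by the
        configured engine.

    Examples
    --------
    >>> from fastconsensus.datasets import gaussian_clusters
    >>> import numpy as np
    >>> ds = gaussian_clusters((15, 15, 15), 50, 6.0, np.random.default_rng(0))
    >>> est = ConsensusClustering(n_resamples=50, k_max=8, random_state=0)
    >>> est.fit(ds.X).k_star_
    3
    """

    def __init__(
        self,
        method: str = "fc",
        algorithm: str = "hier-a",
        n_resamples: int = 250,
        subsample_fraction: float = 0.8,
        k_min: int = 2,
        k_max: int = 30,
        tau: float = 0.03,
        random_state: int | None = None,
    ):
        self.method = method
        self.algorithm = algorithm
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.k_min = k_min
        self.k_max = k_max
        self.tau = tau
        self.random_state = random_state

    def _seed(self) -> int:
        if self.random_state is None:
            return int(np.random.SeedSequence().entropy) & 0x7FFFFFFF
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        raise ValueError("random_state must be an int or None")

    def _config(self, seed: int) -> RunConfig:
        return RunConfig(
            method=self.method,
            algorithm=self.algorithm,
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            k_min=self.k_min,
            k_max=self.k_max,
            tau=self.tau,
            seed=seed,
        )

    def fit(self, X, y=None):
        """Run the configured procedure and predict the number of clusters."""
        X = validate_data(self, X, ensure_min_samples=3)
        seed = self._seed()
        cfg = self._config(seed)
        runner = run_fc if cfg.method == "fc" else run_consensus
        matrices = runner(X, cfg)
        curves = compute_curves(matrices)
        prediction = predict_k(curves.deltas, cfg.tau, cfg.k_max, curves.cdf_curves)

        self.config_ = cfg
        self.consensus_matrices_ = {k: M.entries for k, M in matrices.items()}
        self.cdf_curves_ = curves.cdf_curves
        self.areas_ = curves.areas
        self.deltas_ = curves.deltas
        self.k_star_ = prediction.k_star
        self.stabilized_ = prediction.stabilized
        self.flat_range_ = prediction.flat_range
        self.notes_ = prediction.notes
        self.prediction_ = prediction
        self.labels_ = self._full_data_labels(X, self.k_star_, seed)
        return self

    def _full_data_labels(self, X: np.ndarray, k: int, seed: int) -> np.ndarray:
        if self.algorithm == "kmeans-r":
            return kmeans(X, k, rng=child_rng(seed, 3, k, 0))
        Z = build_dendrogram(pairwise_distances(X), LINKAGE_OF[self.algorithm])
        cut = cut_dendrogram(Z, k)
        if self.algorithm.startswith("hier"):
            return cut
        return kmeans(X, k, init_labels=cut)

    def predict_k(self, tau: float | None = None):
        """Re-apply the plateau rule, optionally at a different threshold."""
        check_is_fitted(self, "deltas_")
        return predict_k(self.deltas_, self.tau if tau is None else tau, self.k_max)
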