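"""The Consensus and FC procedures and their connectivity accumulators.

For a candidate cluster number k, each resampling step h clusters a
perturbed sub-matrix D^(h) and yields a binary connectivity matrix M^(h)
(1 when two items share a cluster) and an indicator matrix I^(h) (1 when
both items were drawn into D^(h)). The consensus matrix is the element-wise
ratio

    M(k)(i, j) = sum_h M^(h)(i, j) / sum_h I^(h)(i, j),

the fraction of co-draws in which a pair co-clustered. ``run_consensus``
is the classical k-outer procedure (fresh resamples for every k);
``run_fc`` switches the two iteration cycles so that one resample — and,
for hierarchical engines, one dendrogram — serves every k. ``run_fc_naive``
is the loop-switched but non-interleaved reference used to validate the
dendrogram-reuse path bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import RunConfig
from .engines import (
    LINKAGE_OF,
    build_dendrogram,
    cut_dendrogram,
    cut_dendrogram_multi,
    kmeans,
    pairwise_distances,
)
from .resampling import child_rng, subsample

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusAccumulator",
    "ConsensusMatrix",
    "accumulate",
    "finalize",
    "run_consensus",
    "run_fc",
    "run_fc_naive",
]

# resample streams: key slot 1; K-means partition streams: key slot 2.
# FC draws one resample per h shared across k, encoded as k = 0.
_RESAMPLE, _KMEANS = 1, 2


@dataclass
class ConsensusAccumulator:
    """Running sums of connectivity (M^(h)) and indicator (I^(h)) matrices."""

    n: int
    co_cluster: np.ndarray = field(init=False)
    co_sampled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.co_cluster = np.zeros((self.n, self.n), dtype=np.int32)
        self.co_sampled = np.zeros((self.n, self.n), dtype=np.int32)


@dataclass
class ConsensusMatrix:
    """Normalized n x n consensus matrix for one candidate k.

    Entries lie in [0, 1]; symmetric; diagonal fixed at 1 by convention.
    """

    k: int
    entries: np.ndarray


def accumulate(
    acc: ConsensusAccumulator, labels: np.ndarray, indices: np.ndarray
) -> ConsensusAccumulator:
    """Fold one resample's clustering into the accumulator.

    For every pair of sampled items the indicator count is incremented; the
    connectivity count is incremented only when the pair shares a label.
    Pairs not drawn into the resample are untouched.
    """
    labels = np.asarray(labels)
    indices = np.asarray(indices)
    if labels.shape[0] != indices.shape[0]:
        raise ValueError(
            f"labeling covers {labels.shape[0]} items but resample has {indices.shape[0]}"
        )
    block = np.ix_(indices, indices)
    acc.co_sampled[block] += 1
    acc.co_cluster[block] += labels[:, None] == labels[None, :]
    return acc


def finalize(acc: ConsensusAccumulator, k: int) -> ConsensusMatrix:
    """Normalize the accumulator into the consensus matrix for k.

    Pairs that were never co-sampled get consensus 0 (no evidence of
    co-clustering) and trigger a warning; the diagonal is set to 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        entries = np.where(
            acc.co_sampled > 0, acc.co_cluster / np.maximum(acc.co_sampled, 1), 0.0
        )
    never = (acc.co_sampled == 0) & ~np.eye(acc.n, dtype=bool)
    if never.any():
        logger.warning(
            "k=%d: %d item pairs were never co-sampled; their consensus is set to 0",
            k,
            int(never.sum()) // 2,
        )
    np.fill_diagonal(entries, 1.0)
    assert np.array_equal(entries, entries.T), "consensus matrix must be symmetric"
    assert entries.min() >= 0.0 and entries.max() <= 1.0, "consensus entries must lie in [0,1]"
    return ConsensusMatrix(k=k, entries=entries)


def _cluster_resample(
    Xs: np.ndarray,
    algorithm: str,
    k: int,
    kmeans_rng: np.random.Generator,
    Z: np.ndarray | None = None,
) -> np.ndarray:
    """One k-cluster solution on a (sub)matrix; builds the dendrogram unless given."""
    if algorithm == "kmeans-r":
        return kmeans(Xs, k, rng=kmeans_rng)
    if Z is None:
        Z = build_dendrogram(pairwise_distances(Xs), LINKAGE_OF[algorithm])
    cut = cut_dendrogram(Z, k)
    if algorithm.startswith("hier"):
        return cut
    return kmeans(Xs, k, init_labels=cut)


def run_consensus(
    X: np.ndarray,
    cfg: RunConfig,
    _resample_rng: Callable[[int, int], np.random.Generator] | None = None,
) -> dict[int, ConsensusMatrix]:
    """Classical k-outer procedure: H fresh resamples drawn for every k.

    Returns one consensus matrix per k in [k_min, k_max]. The total number
    of clustering runs is (k_max - k_min + 1) * H.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    cfg.validate_for(n)
    if _resample_rng is None:
        _resample_rng = lambda k, h: child_rng(cfg.seed, _RESAMPLE, k, h)
    hierarchical_init = cfg.algorithm in LINKAGE_OF
    out: dict[int, ConsensusMatrix] = {}
    for k in cfg.ks:
        acc = ConsensusAccumulator(n)
        for h in range(1, cfg.n_resamples + 1):
            idx = subsample(n, cfg.subsample_fraction, _resample_rng(k, h))
            Xs = X[idx]
            Z = (
                build_dendrogram(pairwise_distances(Xs), LINKAGE_OF[cfg.algorithm])
                if hierarchical_init
                else None
            )
            labels = _cluster_resample(
                Xs, cfg.algorithm, k, child_rng(cfg.seed, _KMEANS, k, h), Z=Z
            )
            accumulate(acc, labels, idx)
        out[k] = finalize(acc, k)
        logger.info("consensus: finished k=%d (%d resamples)", k, cfg.n_resamples)
    return out


def run_fc(
    X: np.ndarray,
    cfg: RunConfig,
    _resample_rng: Callable[[int, int], np.random.Generator] | None = None,
) -> dict[int, ConsensusMatrix]:
    """FC: h-outer procedure with one resample (and one dendrogram) per step.

    For each of the H resamples, hierarchical engines build a single merge
    tree and harvest its cut at every k in [k_min, k_max]; K-means variants
    reuse the same tree (or random partitions) for their initializations.
    Hierarchical engines therefore build H dendrograms in total instead of
    (k_max - k_min + 1) * H.
    """
    return _run_fc(X, cfg, reuse_dendrogram=True, _resample_rng=_resample_rng)


def run_fc_naive(
    X: np.ndarray,
    cfg: RunConfig,
    _resample_rng: Callable[[int, int], np.random.Generator] | None = None,
) -> dict[int, ConsensusMatrix]:
    """Loop-switched reference that re-clusters each resample from scratch per k.

    Identical sampling and K-means streams as :func:`run_fc`; used to verify
    that dendrogram reuse changes nothing in the output.
    """
    return _run_fc(X, cfg, reuse_dendrogram=False, _resample_rng=_resample_rng)


def _run_fc(
    X: np.ndarray,
    cfg: RunConfig,
    reuse_dendrogram: bool,
    _resample_rng: Callable[[int, int], np.random.Generator] | None = None,
) -> dict[int, ConsensusMatrix]:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    cfg.validate_for(n)
    if _resample_rng is None:
        _resample_rng = lambda k, h: child_rng(cfg.seed, _RESAMPLE, k, h)
    ks = cfg.ks
    hierarchical_init = cfg.algorithm in LINKAGE_OF
    accs = {k: ConsensusAccumulator(n) for k in ks}
    for h in range(1, cfg.n_resamples + 1):
        idx = subsample(n, cfg.subsample_fraction, _resample_rng(0, h))
        Xs = X[idx]
        if hierarchical_init and reuse_dendrogram:
            Z = build_dendrogram(pairwise_distances(Xs), LINKAGE_OF[cfg.algorithm])
            cuts = cut_dendrogram_multi(Z, ks)
            for k in ks:
                labels = (
                    cuts[k]
                    if cfg.algorithm.startswith("hier")
                    else kmeans(Xs, k, init_labels=cuts[k])
                )
                accumulate(accs[k], labels, idx)
        else:
            for k in ks:
                labels = _cluster_resample(
                    Xs, cfg.algorithm, k, child_rng(cfg.seed, _KMEANS, k, h)
                )
                accumulate(accs[k], labels, idx)
        logger.info("fc: finished resample h=%d/%d", h, cfg.n_resamples)
    return {k: finalize(accs[k], k) for k in ks}
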