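import logging

import numpy as np
import pytest

from fastconsensus.config import RunConfig
from fastconsensus.consensus import (
    ConsensusAccumulator,
    accumulate,
    finalize,
    run_consensus,
    run_fc,
    run_fc_naive,
)
from fastconsensus.engines import build_dendrogram, cut_dendrogram, pairwise_distances
from fastconsensus.resampling import child_rng


def connectivity_of(labels):
    labels = np.asarray(labels)
    M = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(M, 1.0)
    return M


def test_accumulate_updates_only_sampled_pairs():
    acc = ConsensusAccumulator(4)
    accumulate(acc, labels=np.array([0, 0, 1]), indices=np.array([0, 1, 2]))
    expected_sampled = np.zeros((4, 4))
    expected_sampled[np.ix_([0, 1, 2], [0, 1, 2])] = 1
    assert np.array_equal(acc.co_sampled, expected_sampled)
    assert acc.co_cluster[0, 1] == acc.co_cluster[1, 0] == 1
    assert acc.co_cluster[0, 2] == acc.co_cluster[1, 2] == 0
    assert np.all(acc.co_cluster[3, :] == 0) and np.all(acc.co_sampled[3, :] == 0)


def test_accumulate_all_items_one_cluster():
    acc = ConsensusAccumulator(3)
    accumulate(acc, np.zeros(3, dtype=int), np.arange(3))
    off = ~np.eye(3, dtype=bool)
    assert np.all(acc.co_cluster[off] == 1) and np.all(acc.co_sampled[off] == 1)


def test_accumulate_is_additive():
    acc = ConsensusAccumulator(4)
    for _ in range(2):
        accumulate(acc, np.array([0, 0, 1]), np.array([0, 1, 3]))
    assert acc.co_cluster[0, 1] == 2
    assert acc.co_sampled[0, 3] == 2


def test_accumulate_size_mismatch_rejected():
    acc = ConsensusAccumulator(4)
    with pytest.raises(ValueError, match="resample"):
        accumulate(acc, np.array([0, 0]), np.array([0, 1, 2]))


def test_finalize_ratio_and_diagonal():
    acc = ConsensusAccumulator(3)
    accumulate(acc, np.array([0, 1]), np.array([0, 1]))
    accumulate(acc, np.array([0, 0]), np.array([0, 1]))
    M = finalize(acc, k=2)
    assert M.entries[0, 1] == pytest.approx(0.5)
    assert np.all(np.diag(M.entries) == 1.0)


def test_finalize_never_cosampled_is_zero_with_warning(caplog):
    acc = ConsensusAccumulator(3)
    accumulate(acc, np.array([0, 0]), np.array([0, 1]))
    with caplog.at_level(logging.WARNING, logger="fastconsensus.consensus"):
        M = finalize(acc, k=2)
    assert M.entries[0, 2] == 0.0 and M.entries[1, 2] == 0.0
    assert any("never co-sampled" in rec.message for rec in caplog.records)


@pytest.mark.parametrize("method", ["consensus", "fc"])
@pytest.mark.parametrize("algorithm", ["hier-a", "hier-c", "hier-s"])
def test_p_one_degenerates_to_single_clustering(two_gaussian_12, method, algorithm):
    """With p=1 every resample is D itself: the consensus matrix is binary and
    equals the connectivity matrix of one direct clustering, for any H."""
    X = two_gaussian_12.X
    cfg = RunConfig(
        method=method, algorithm=algorithm, n_resamples=3,
        subsample_fraction=1.0, k_min=2, k_max=4, seed=5,
    )
    runner = run_fc if method == "fc" else run_consensus
    out = runner(X, cfg)
    Z = build_dendrogram(pairwise_distances(X), {"hier-a": "average", "hier-c": "complete", "hier-s": "single"}[algorithm])
    for k in (2, 3, 4):
        entries = out[k].entries
        assert set(np.unique(entries).tolist()) <= {0.0, 1.0}
        assert np.array_equal(entries, connectivity_of(cut_dendrogram(Z, k)))


def test_single_resample_gives_binary_matrix(two_gaussian_12):
    cfg = RunConfig(method="fc", algorithm="hier-a", n_resamples=1,
                    subsample_fraction=0.8, k_min=2, k_max=3, seed=1)
    out = run_fc(two_gaussian_12.X, cfg)
    assert set(np.unique(out[2].entries).tolist()) <= {0.0, 1.0}


def test_separated_clusters_give_bimodal_consensus(two_gaussian_12):
    """Well-separated two-Gaussian data: within-class consensus near 1,
    between-class near 0 at k=2."""
    ds = two_gaussian_12
    cfg = RunConfig(method="fc", algorithm="hier-a", n_resamples=50,
                    subsample_fraction=0.8, k_min=2, k_max=2, seed=3)
    entries = run_fc(ds.X, cfg)[2].entries
    same = ds.true_labels[:, None] == ds.true_labels[None, :]
    off = ~np.eye(ds.n, dtype=bool)
    assert entries[same & off].mean() >= 0.9
    assert entries[~same].mean() <= 0.1


@pytest.mark.parametrize("algorithm", ["hier-a", "hier-c", "hier-s", "kmeans-a", "kmeans-r"])
def test_fc_fast_path_equals_naive_reference(algorithm):
    """Dendrogram reuse must not change a single consensus entry."""
    rng = np.random.default_rng(17)
    for trial in range(2):
        n = int(rng.integers(15, 31))
        X = rng.standard_normal((n, 4))
        cfg = RunConfig(method="fc", algorithm=algorithm, n_resamples=8,
                        subsample_fraction=0.8, k_min=2, k_max=6, seed=trial)
        fast = run_fc(X, cfg)
        naive = run_fc_naive(X, cfg)
        for k in cfg.ks:
            assert np.array_equal(fast[k].entries, naive[k].entries), (algorithm, trial, k)


def test_consensus_equals_fc_with_shared_streams(two_gaussian_12):
    """With H=1 and a shared resample stream, the k-outer and h-outer loops
    visit exactly the same clustering problems."""
    X = two_gaussian_12.X
    cfg = RunConfig(method="fc", algorithm="hier-a", n_resamples=1,
                    subsample_fraction=0.8, k_min=2, k_max=5, seed=9)
    shared = lambda k, h: child_rng(cfg.seed, 1, 0, h)
    a = run_consensus(X, cfg, _resample_rng=shared)
    b = run_fc(X, cfg, _resample_rng=shared)
    for k in cfg.ks:
        assert np.array_equal(a[k].entries, b[k].entries)


def test_consensus_matrices_symmetric_unit_range(two_gaussian_12):
    cfg = RunConfig(method="consensus", algorithm="kmeans-r", n_resamples=10,
                    subsample_fraction=0.8, k_min=2, k_max=4, seed=2)
    out = run_consensus(two_gaussian_12.X, cfg)
    for M in out.values():
        assert np.array_equal(M.entries, M.entries.T)
        assert M.entries.min() >= 0.0 and M.entries.max() <= 1.0
        assert np.all(np.diag(M.entries) == 1.0)


def test_hierarchical_connectivity_nested_within_resample(two_gaussian_12):
    """Within one resample, pairs that co-cluster at k stay together at k' < k."""
    X = two_gaussian_12.X
    Z = build_dendrogram(pairwise_distances(X), "average")
    prev = None
    for k in range(X.shape[0], 1, -1):
        conn = connectivity_of(cut_dendrogram(Z, k))
        if prev is not None:
            assert np.all(conn >= prev)  # coarsening only adds connections
        prev = conn
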