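import numpy as np
import pytest

from fastconsensus.datasets import gaussian_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gaussian_12(rng):
    """12 items in two well-separated Gaussian clusters."""
    return gaussian_clusters((6, 6), n_dims=5, separation=6.0, rng=rng)


@pytest.fixture
def three_gaussian_60():
    """60 items in three well-separated high-dimensional Gaussian clusters."""
    return gaussian_clusters((20, 20, 20), n_dims=200, separation=6.0,
                             rng=np.random.default_rng(777))


@pytest.fixture
def tiny_tsv(tmp_path):
    """3 items x 2 conditions expression matrix on disk."""
    path = tmp_path / "m.tsv"
    path.write_text(
        "id\tc1\tc2\n"
        "g1\t1\t2\n"
        "g2\t3\t4\n"
        "g3\t5\t6\n"
    )
    return path
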