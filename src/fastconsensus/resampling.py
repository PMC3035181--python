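"""Row-subsampling scheme and the seeded stream discipline.

Each resampling step draws, uniformly at random and without replacement,
``floor(p * n)`` of the n items (rows) of the dataset; clustering the induced
sub-matrix yields one perturbed clustering solution. All randomness flows
through numpy Generator child streams derived deterministically from one
master seed, so every resample is reproducible and the Consensus and FC
procedures can be made to share exact samples in equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["subsample", "child_rng"]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream for the master ``seed`` and an integer key.

    Key slots used by the procedures: ``(1, k, h)`` for resample draws
    (k = 0 in the FC path, which shares one resample across all k) and
    ``(2, k, h)`` for K-means random-partition draws.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def subsample(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one resample: ``floor(p*n)`` distinct item indices, sorted.

    Every subset of that size is equally probable. Raises ValueError when the
    sample would have fewer than 2 items (no pair to accumulate).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    size = math.floor(p * n)
    if size < 2:
        raise ValueError(f"sample too small: floor(p*n) = {size} < 2")
    indices = rng.choice(n, size=size, replace=False)
    indices.sort()
    return indices
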