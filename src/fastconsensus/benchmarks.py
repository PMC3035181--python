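"""Seeded gold-k benchmark runs on the synthetic presets."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datasets import make_preset
from .estimator import ConsensusClustering

__all__ = ["predict_preset_k", "gold_k_runs"]

#: key slot separating dataset generation from the run's resampling streams
_DATA_KEY = 99


def predict_preset_k(
    name: str,
    seed: int,
    method: str = "fc",
    algorithm: str = "hier-a",
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    k_min: int = 2,
    k_max: int = 10,
    tau: float = 0.03,
) -> tuple[int, int]:
    """Generate one preset instance with ``seed`` and predict its k*.

    Returns ``(k_star, true_k)``. The dataset is drawn from a child stream
    of ``seed`` distinct from the resampling streams of the run itself.
    """
    dataset = make_preset(name, np.random.default_rng([int(seed) & 0x7FFFFFFF, _DATA_KEY]))
    est = ConsensusClustering(
        method=method,
        algorithm=algorithm,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        k_min=k_min,
        k_max=k_max,
        tau=tau,
        random_state=int(seed) & 0x7FFFFFFF,
    )
    est.fit(dataset.X)
    return est.k_star_, dataset.true_k


def gold_k_runs(name: str, seeds: Sequence[int], **kwargs) -> list[int]:
    """Predicted k* for one preset across several seeds."""
    return [predict_preset_k(name, s, **kwargs)[0] for s in seeds]
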