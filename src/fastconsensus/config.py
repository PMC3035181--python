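"""Run configuration for consensus-clustering runs.

A run is fully described by the procedure variant (``consensus`` or ``fc``),
the clustering engine, the resampling parameters H (number of resampling
steps) and p (subsampling fraction), the candidate range ``[k_min, k_max]``
for the number of clusters, the plateau threshold ``tau`` used by the
automatic k* rule, and a master seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

METHODS = ("consensus", "fc")

#: engine tokens: agglomerative hierarchical clustering under average /
#: complete / single linkage, and Lloyd K-means initialized from a random
#: partition (-r) or from the cut of a hierarchical dendrogram (-a/-c/-s).
ALGORITHMS = (
    "hier-a",
    "hier-c",
    "hier-s",
    "kmeans-r",
    "kmeans-a",
    "kmeans-c",
    "kmeans-s",
)


@dataclass
class RunConfig:
    """Parameters of one consensus / FC run.

    Defaults follow the robust setting for small-to-medium expression
    datasets: H = 250 resampling steps, p = 80% subsampling, candidate
    cluster numbers in [2, 30].
    """

    method: str = "fc"
    algorithm: str = "hier-a"
    n_resamples: int = 250  # H
    subsample_fraction: float = 0.80  # p
    k_min: int = 2
    k_max: int = 30
    tau: float = 0.03
    seed: int = 0
    transpose: bool = False
    out_dir: str = "fastconsensus_out"

    @property
    def ks(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))

    def validate(self) -> None:
        """Check the data-independent invariants; raise ValueError on violation."""
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.n_resamples < 1:
            raise ValueError(f"H (n_resamples) must be >= 1, got {self.n_resamples}")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError(
                f"p (subsample_fraction) must be in (0, 1], got {self.subsample_fraction}"
            )
        if self.k_min < 2:
            raise ValueError(f"k_min must be >= 2, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(f"k_max must be >= k_min, got k_max={self.k_max} < k_min={self.k_min}")
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")

    def validate_for(self, n_items: int) -> None:
        """Check invariants that depend on the dataset size ``n_items``.

        A k-cluster solution needs at least k sampled items, so k_max may not
        exceed floor(p * n).
        """
        self.validate()
        sample_size = math.floor(self.subsample_fraction * n_items)
        if sample_size < 2:
            raise ValueError(
                f"sample too small: floor(p*n) = {sample_size} < 2 (n={n_items}, "
                f"p={self.subsample_fraction})"
            )
        if self.k_max > sample_size:
            raise ValueError(
                f"k_max must satisfy k_max <= floor(p*n) = {sample_size} "
                f"(n={n_items}, p={self.subsample_fraction}); got k_max={self.k_max}"
            )

    def to_dict(self) -> dict:
        return asdict(self)
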