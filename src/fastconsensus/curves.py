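"""CDF curves, area statistics, the Δ series, and the plateau rule for k*.

Let m = n(n-1)/2 and x_1 <= ... <= x_m be the sorted upper-triangle entries
of a consensus matrix. The empirical CDF over [0, 1] is

    CDF(c) = #{(i, j), i < j : M(i, j) <= c} / m,

its area is estimated by the discrete sum

    A(k) = sum_{i=2}^{m} (x_i - x_{i-1}) * CDF(x_i),

and the proportional increase of that area is

    Delta(k) = A(2)                      for k = 2,
               (A(k+1) - A(k)) / A(k)    for k > 2.

Under stable clustering the CDF is bimodal at {0, 1}; A(k) grows markedly
while k is below the true cluster number and flattens beyond it, so the
point where the Δ curve stabilizes predicts k*. The forward-difference form
means Δ is defined on {2} ∪ [3, k_max - 1] and has no value at k_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CDFCurve",
    "CurveSet",
    "Prediction",
    "empirical_cdf",
    "cdf_area",
    "delta_series",
    "predict_k",
    "compute_curves",
    "consensus_to_dissimilarity",
]


@dataclass
class CDFCurve:
    """Empirical CDF of the m upper-triangle consensus entries for one k."""

    k: int
    xs: np.ndarray  # sorted entries, duplicates kept
    cdf: np.ndarray  # CDF(x_i) for each i; ties share one value


@dataclass
class CurveSet:
    """Areas A(k), Δ(k) series and CDF curves over the candidate k grid."""

    ks: list[int]
    areas: dict[int, float]
    deltas: dict[int, float]
    cdf_curves: dict[int, CDFCurve]


@dataclass
class Prediction:
    """Predicted cluster number and plateau diagnostics."""

    k_star: int
    tau: float
    stabilized: bool
    flat_range: tuple[int, int] | None
    notes: list[str] = field(default_factory=list)


def empirical_cdf(M: ConsensusMatrix) -> CDFCurve:
    """CDF of the upper-triangle entries of one consensus matrix."""
    entries = np.asarray(M.entries)
    n = entries.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    xs = np.sort(entries[np.triu_indices(n, k=1)])
    m = xs.size
    cdf = np.searchsorted(xs, xs, side="right") / m
    return CDFCurve(k=M.k, xs=xs, cdf=cdf)


def cdf_area(curve: CDFCurve) -> float:
    """Discrete-sum estimate A of the area under one CDF curve."""
    return float(np.sum(np.diff(curve.xs) * curve.cdf[1:]))


def delta_series(areas: dict[int, float]) -> dict[int, float]:
    """Proportional-increase series Δ(k) from areas on a contiguous k grid.

    Δ(2) = A(2); Δ(k) = (A(k+1) - A(k)) / A(k) for k >= 3. The series ends
    at k_max - 1 (the forward difference needs A(k+1)). Raises on a zero
    area used as a denominator, which happens only for a constant consensus
    matrix.
    """
    ks = sorted(areas)
    if not ks:
        raise ValueError("empty area series")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("areas must cover a contiguous k grid")
    deltas: dict[int, float] = {}
    if ks[0] == 2:
        deltas[2] = areas[2]
    for k in range(max(ks[0], 3), ks[-1]):
        if areas[k] <= 0.0:
            raise ValueError(f"degenerate area series: A({k}) = {areas[k]}")
        deltas[k] = (areas[k + 1] - areas[k]) / areas[k]
    return deltas


def predict_k(
    deltas: dict[int, float],
    tau: float,
    k_max: int,
    cdf_curves: dict[int, CDFCurve] | None = None,
) -> Prediction:
    """Plateau rule: k* is the smallest k >= 3 with Δ(j) <= tau for all j >= k.

    The rule operationalizes "the abscissa where the Δ curve starts to
    stabilize". When no such k exists the prediction falls back to
    k_max - 1 with ``stabilized=False``; the CDF curves remain available for
    visual disambiguation. Negative Δ values (possible since only observed,
    never guaranteed, to be non-negative) are recorded in the notes.
    """
    if not deltas:
        raise ValueError("empty delta series")
    notes: list[str] = []
    negative = sorted(k for k, d in deltas.items() if d < 0)
    if negative:
        notes.append(f"negative delta values at k = {negative}")
    if 2 in deltas and deltas[2] <= tau:
        notes.append(f"delta(2) = A(2) = {deltas[2]:.6g} is already <= tau")
    scan = sorted(k for k in deltas if k >= 3)
    k_star = None
    for k in scan:
        if all(deltas[j] <= tau for j in scan if j >= k):
            k_star = k
            break
    stabilized = k_star is not None
    if not stabilized:
        k_star = k_max - 1
        notes.append("no plateau: delta never stabilized below tau; k* set to k_max - 1")
    flat = [k for k in scan if deltas[k] <= tau]
    flat_range = None
    if flat:
        # maximal contiguous run (earliest on ties)
        best_len, start = 0, flat[0]
        run_start = flat[0]
        prev = flat[0]
        for k in flat[1:] + [None]:
            if k is not None and k == prev + 1:
                prev = k
                continue
            if prev - run_start + 1 > best_len:
                best_len, start = prev - run_start + 1, run_start
                flat_range = (start, start + best_len - 1)
            if k is not None:
                run_start = prev = k
        if flat_range is None:
            flat_range = (flat[0], flat[0])
    return Prediction(
        k_star=int(k_star),
        tau=tau,
        stabilized=stabilized,
        flat_range=flat_range,
        notes=notes,
    )


def compute_curves(matrices: dict[int, ConsensusMatrix]) -> CurveSet:
    """CDF curves, areas and Δ series for a family of consensus matrices."""
    ks = sorted(matrices)
    cdf_curves = {k: empirical_cdf(matrices[k]) for k in ks}
    areas = {k: cdf_area(cdf_curves[k]) for k in ks}
    deltas = delta_series(areas)
    return CurveSet(ks=ks, areas=areas, deltas=deltas, cdf_curves=cdf_curves)


def consensus_to_dissimilarity(M: ConsensusMatrix) -> np.ndarray:
    """1 - consensus: a symmetric, zero-diagonal dissimilarity matrix.

    Valid input for :func:`fastconsensus.engines.build_dendrogram`, letting
    the consensus matrix itself drive a final clustering.
    """
    out = 1.0 - np.asarray(M.entries, dtype=float)
    np.fill_diagonal(out, 0.0)
    return out
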