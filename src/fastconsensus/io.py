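"""Reading expression matrices and writing run artifacts.

The input dialect is a tab-delimited table with one header row of condition
ids and a leading column of item ids; values must parse as finite decimal
numbers (missing values are rejected, not imputed). Rows are the items to
cluster; sample-clustering studies are handled by the transpose flag.
Numeric outputs are printed with 12 significant digits so that a write /
read round trip is exact at printed precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .consensus import ConsensusMatrix
from .curves import CurveSet, Prediction

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "read_consensus_matrix",
    "write_outputs",
]

_FLOAT_FMT = "%.12g"


@dataclass
class ExpressionMatrix:
    """n items x d conditions of real values, with labels on both axes."""

    values: np.ndarray
    item_ids: list[str]
    condition_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def read_expression_matrix(path: str | os.PathLike, transpose: bool = False) -> ExpressionMatrix:
    """Parse a tab-delimited expression matrix.

    Raises ValueError naming the offending line for ragged rows and the
    offending row/column for non-numeric or non-finite cells. With
    ``transpose`` the matrix is flipped before return so that items are
    always rows downstream.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [line.rstrip("\n").rstrip("\r") for line in fh]
    lines = [line for line in lines if line.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: empty matrix (need a header row and at least one data row)")
    header = lines[0].split("\t")
    condition_ids = header[1:]
    d = len(condition_ids)
    if d == 0:
        raise ValueError(f"{path}: header row has no condition columns")
    item_ids: list[str] = []
    rows: list[list[float]] = []
    for line_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != d + 1:
            raise ValueError(
                f"{path}: line {line_no}: expected {d + 1} tab-separated fields, got {len(parts)}"
            )
        item_ids.append(parts[0])
        row = []
        for j, token in enumerate(parts[1:]):
            try:
                value = float(token)
            except ValueError:
                value = np.nan
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}: non-numeric value {token!r} at row {parts[0]!r} "
                    f"(line {line_no}), column {condition_ids[j]!r}"
                )
            row.append(value)
        rows.append(row)
    values = np.asarray(rows, dtype=float)
    if transpose:
        values = values.T
        item_ids, condition_ids = condition_ids, item_ids
    if values.shape[0] < 3:
        raise ValueError(
            f"{path}: need at least 3 items to cluster, got {values.shape[0]}"
        )
    return ExpressionMatrix(values=values, item_ids=item_ids, condition_ids=condition_ids)


def read_consensus_matrix(path: str | os.PathLike) -> np.ndarray:
    """Re-parse a consensus matrix written by :func:`write_outputs`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float)


def _write_matrix(path: Path, entries: np.ndarray, ids: list[str]) -> None:
    frame = pd.DataFrame(entries, index=ids, columns=ids)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_outputs(
    out_dir: str | os.PathLike,
    matrices: dict[int, ConsensusMatrix],
    curves: CurveSet,
    prediction: Prediction,
    config: RunConfig | None = None,
    item_ids: list[str] | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write per-k consensus matrices, curve tables, the prediction, and plots.

    Produces ``consensus_k<k>.tsv`` (n x n with item ids), ``curves.tsv``
    (columns k, A, delta; delta empty where undefined), ``cdf_k<k>.tsv``
    (columns x, CDF), ``prediction.json`` and, when ``plots`` is set, PNGs of
    the CDF family and the Δ curve. Returns the written paths.
    """
    if not matrices or not curves.ks:
        raise ValueError("empty k range: nothing to write")
    if sorted(matrices) != curves.ks:
        raise ValueError("matrices and curves disagree on the k grid")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = next(iter(matrices.values())).entries.shape[0]
    ids = item_ids if item_ids is not None else [f"item_{i}" for i in range(n)]
    written: list[Path] = []

    for k, M in sorted(matrices.items()):
        path = out / f"consensus_k{k}.tsv"
        _write_matrix(path, M.entries, ids)
        written.append(path)

    curves_path = out / "curves.tsv"
    with open(curves_path, "w", encoding="utf-8") as fh:
        fh.write("k\tA\tdelta\n")
        for k in curves.ks:
            delta = curves.deltas.get(k)
            delta_s = "" if delta is None else _FLOAT_FMT % delta
            fh.write(f"{k}\t{_FLOAT_FMT % curves.areas[k]}\t{delta_s}\n")
    written.append(curves_path)

    for k in curves.ks:
        curve = curves.cdf_curves[k]
        path = out / f"cdf_k{k}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("x\tCDF\n")
            for x, c in zip(curve.xs, curve.cdf):
                fh.write(f"{_FLOAT_FMT % x}\t{_FLOAT_FMT % c}\n")
        written.append(path)

    pred_path = out / "prediction.json"
    payload = {
        "k_star": prediction.k_star,
        "tau": prediction.tau,
        "stabilized": prediction.stabilized,
        "flat_range": list(prediction.flat_range) if prediction.flat_range else None,
        "notes": prediction.notes,
        "config": config.to_dict() if config is not None else None,
    }
    with open(pred_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(pred_path)

    if plots:
        written.extend(_write_plots(out, curves, prediction))
    return written


def _write_plots(out: Path, curves: CurveSet, prediction: Prediction) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cdf_path = out / "cdf_curves.png"
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for k in curves.ks:
        curve = curves.cdf_curves[k]
        ax.step(curve.xs, curve.cdf, where="post", label=f"k={k}", lw=1)
    ax.set_xlabel("consensus index value")
    ax.set_ylabel("CDF")
    ax.set_title("Empirical CDF of consensus entries")
    if len(curves.ks) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(cdf_path, dpi=120)
    plt.close(fig)

    delta_path = out / "delta_curve.png"
    ks = sorted(curves.deltas)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(ks, [curves.deltas[k] for k in ks], marker="o")
    ax.axhline(prediction.tau, color="grey", ls="--", lw=1, label=f"tau={prediction.tau}")
    ax.axvline(prediction.k_star, color="red", ls=":", lw=1, label=f"k*={prediction.k_star}")
    ax.set_xlabel("k")
    ax.set_ylabel("delta(k)")
    ax.set_title("Proportional increase of the CDF area")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(delta_path, dpi=120)
    plt.close(fig)
    return [cdf_path, delta_path]
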