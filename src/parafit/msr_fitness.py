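"""Mean Squared Residue (MSR) of an expression (sub)matrix.

For a matrix B with I rows and J columns the residue of a cell is

    r_ij = b_ij - rowmean_i - colmean_j + overallmean

and the MSR is the mean of the squared residues. Lower is better;
an exactly additive matrix (b_ij = a_i + c_j) has MSR 0.

All computations are double precision.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import Bicluster, ExpressionMatrix, extract_submatrix

__all__ = [
    "MsrBreakdown",
    "row_means",
    "col_means",
    "overall_mean",
    "residues",
    "msr",
    "msr_breakdown",
    "msr_of_bicluster",
]


def _values(m) -> np.ndarray:
    v = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2-D matrix, got shape {v.shape}")
    return v


def row_means(m) -> np.ndarray:
    """Mean of each row: entry i is (sum_j b_ij) / J."""
    return _values(m).mean(axis=1)


def col_means(m) -> np.ndarray:
    """Mean of each column: entry j is (sum_i b_ij) / I."""
    return _values(m).mean(axis=0)


def overall_mean(m) -> float:
    """Mean of the whole matrix: (sum_ij b_ij) / (I*J)."""
    return float(_values(m).mean())


def residues(m) -> np.ndarray:
    """Residue matrix r_ij = b_ij - rowmean_i - colmean_j + overallmean."""
    v = _values(m)
    return v - v.mean(axis=1, keepdims=True) - v.mean(axis=0, keepdims=True) + v.mean()


def msr(m) -> float:
    """Mean squared residue (non-negative scalar)."""
    r = residues(m)
    return float((r * r).mean())


@dataclass(frozen=True)
class MsrBreakdown:
    """All intermediates of the MSR computation."""

    row_sums: np.ndarray
    col_sums: np.ndarray
    total_sum: float
    row_means: np.ndarray
    col_means: np.ndarray
    overall_mean: float
    residues: np.ndarray
    msr: float


def msr_breakdown(m) -> MsrBreakdown:
    """MSR together with every intermediate (sums, means, residues)."""
    v = _values(m)
    row_sums = v.sum(axis=1)
    col_sums = v.sum(axis=0)
    total = float(v.sum())
    rm = v.mean(axis=1)
    cm = v.mean(axis=0)
    om = float(v.mean())
    r = v - rm[:, None] - cm[None, :] + om
    return MsrBreakdown(
        row_sums=row_sums,
        col_sums=col_sums,
        total_sum=total,
        row_means=rm,
        col_means=cm,
        overall_mean=om,
        residues=r,
        msr=float((r * r).mean()),
    )


def msr_of_bicluster(parent: ExpressionMatrix, b: Bicluster) -> float:
    """MSR of the submatrix of ``parent`` selected by ``b``."""
    return msr(extract_submatrix(parent, b))
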