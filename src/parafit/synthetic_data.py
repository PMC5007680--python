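"""Seeded generators for synthetic expression data.

Two generators: matrices with a planted bicluster (constant, additive or
shifted structure plus Gaussian noise on a standard-normal background)
and balanced two-class microarray-like datasets with a small informative
gene subset. Both return ground truth alongside the data and are pure
functions of their spec, seed included.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import Bicluster, ExpressionMatrix, GeneSubset, LabeledDataset

__all__ = ["PlantSpec", "make_bicluster_matrix", "make_classification_dataset"]

STRUCTURES = ("constant", "additive", "shifted")


@dataclass(frozen=True)
class PlantSpec:
    """Specification of a matrix with one planted bicluster.

    ``signal`` is the constant level (structure=constant), the standard
    deviation of the row/column effects (additive), or the mean shift
    added to the background (shifted). ``noise_sd`` is the SD of the
    extra Gaussian noise on planted cells (constant/additive only; the
    shifted structure keeps the background values as its noise).
    """

    shape: tuple[int, int]
    rows: tuple[int, ...]
    cols: tuple[int, ...]
    structure: str = "additive"
    signal: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        I, J = self.shape
        if I < 1 or J < 1:
            raise ValueError(f"shape must be at least 1x1, got {self.shape}")
        rows = tuple(sorted(int(i) for i in self.rows))
        cols = tuple(sorted(int(j) for j in self.cols))
        if not rows or not cols:
            raise ValueError("planted bicluster needs at least one row and one column")
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("planted index sets must be unique")
        if rows[0] < 0 or rows[-1] >= I or cols[0] < 0 or cols[-1] >= J:
            raise ValueError(f"planted indices out of bounds for shape {self.shape}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)


def make_bicluster_matrix(spec: PlantSpec) -> tuple[ExpressionMatrix, Bicluster]:
    """Generate a matrix with the planted bicluster of ``spec``.

    Background cells are i.i.d. standard normal. Planted cells are
    replaced according to the structure; deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    I, J = spec.shape
    values = rng.normal(0.0, 1.0, size=(I, J))
    ridx = np.asarray(spec.rows)
    cidx = np.asarray(spec.cols)
    block_shape = (len(ridx), len(cidx))
    if spec.structure == "constant":
        block = spec.signal + rng.normal(0.0, spec.noise_sd, size=block_shape)
        values[np.ix_(ridx, cidx)] = block
    elif spec.structure == "additive":
        a = rng.normal(0.0, spec.signal, size=len(ridx))
        c = rng.normal(0.0, spec.signal, size=len(cidx))
        block = a[:, None] + c[None, :] + rng.normal(0.0, spec.noise_sd, size=block_shape)
        values[np.ix_(ridx, cidx)] = block
    else:  # shifted: keep the background as the noise, add a mean shift
        values[np.ix_(ridx, cidx)] += spec.signal
    matrix = ExpressionMatrix(values)
    return matrix, Bicluster(spec.rows, spec.cols)


def make_classification_dataset(N: int, M: int, k: int, effect: float,
                                seed: int = 0) -> tuple[LabeledDataset, GeneSubset]:
    """Generate a balanced two-class dataset with k informative genes.

    N samples (N even, N/2 per class) by M genes of unit-variance
    Gaussian noise; the k informative genes differ between classes by
    ``effect`` noise-SD units in the mean. Deterministic per seed.
    """
    if N < 4 or N % 2:
        raise ValueError(f"N must be even and >= 4, got {N}")
    if not 1 <= k <= M:
        raise ValueError(f"need 1 <= k <= M, got k={k}, M={M}")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(N, M))
    informative = np.sort(rng.choice(M, size=k, replace=False))
    half = N // 2
    X[half:, informative] += float(effect)
    labels = ("A",) * half + ("B",) * half
    matrix = ExpressionMatrix(
        X,
        row_ids=tuple(f"s{i + 1}" for i in range(N)),
        col_ids=tuple(f"g{j + 1}" for j in range(M)),
    )
    return LabeledDataset(matrix, labels), GeneSubset.from_indices(informative, M)
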