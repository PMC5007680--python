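"""Expression-matrix I/O and the core index types.

Matrices are stored with rows = experimental conditions / samples and
columns = genes. The on-disk format is delimited text (TSV by default)
with one optional header row of gene ids and one optional leading column
of condition ids. Class labels live in a separate two-column file
(sample_id, class).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "Bicluster",
    "GeneSubset",
    "LabeledDataset",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "load_labeled_dataset",
    "extract_submatrix",
]


class ParseError(ValueError):
    """Raised when a delimited-text matrix or labels file is malformed."""


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


@dataclass(frozen=True)
class ExpressionMatrix:
    """A real-valued I x J matrix: I conditions (rows) by J genes (columns)."""

    values: np.ndarray
    row_ids: tuple[str, ...] = ()
    col_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={values.ndim}")
        n_rows, n_cols = values.shape
        if n_rows < 1 or n_cols < 1:
            raise ValueError(f"matrix must be at least 1x1, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        row_ids = tuple(self.row_ids) or tuple(f"cond{i + 1}" for i in range(n_rows))
        col_ids = tuple(self.col_ids) or tuple(f"gene{j + 1}" for j in range(n_cols))
        if len(row_ids) != n_rows:
            raise ValueError(f"{len(row_ids)} row ids for {n_rows} rows")
        if len(col_ids) != n_cols:
            raise ValueError(f"{len(col_ids)} column ids for {n_cols} columns")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", row_ids)
        object.__setattr__(self, "col_ids", col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Bicluster:
    """An index-mask view: a subset of rows and a subset of columns.

    Indices are 0-based, unique and stored sorted (canonical form).
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, idx in (("rows", self.rows), ("cols", self.cols)):
            idx = tuple(int(i) for i in idx)
            if len(idx) < 1:
                raise ValueError(f"bicluster needs at least one entry in {name}")
            if len(set(idx)) != len(idx):
                raise ValueError(f"duplicate indices in bicluster {name}: {idx}")
            if any(i < 0 for i in idx):
                raise ValueError(f"negative index in bicluster {name}: {idx}")
            object.__setattr__(self, name, tuple(sorted(idx)))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.cols))

    def check_bounds(self, n_rows: int, n_cols: int) -> None:
        if self.rows[-1] >= n_rows:
            raise IndexError(
                f"bicluster row index {self.rows[-1]} out of range for {n_rows} rows"
            )
        if self.cols[-1] >= n_cols:
            raise IndexError(
                f"bicluster column index {self.cols[-1]} out of range for {n_cols} columns"
            )


@dataclass(frozen=True)
class GeneSubset:
    """A boolean mask over the M genes of a dataset."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool).ravel()
        if mask.size < 1:
            raise ValueError("gene mask must have length >= 1")
        object.__setattr__(self, "mask", mask)

    @property
    def M(self) -> int:
        return int(self.mask.size)

    @property
    def R(self) -> int:
        """Number of selected genes (popcount of the mask)."""
        return int(self.mask.sum())

    def indices(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.mask))

    @classmethod
    def from_indices(cls, indices: Iterable[int], M: int) -> "GeneSubset":
        mask = np.zeros(int(M), dtype=bool)
        for i in indices:
            i = int(i)
            if not 0 <= i < M:
                raise ValueError(f"gene index {i} out of range for M={M}")
            mask[i] = True
        return cls(mask)

    @classmethod
    def from_bitstring(cls, bits: str) -> "GeneSubset":
        if not bits or set(bits) - {"0", "1"}:
            raise ValueError(f"not a bitstring: {bits!r}")
        return cls(np.array([c == "1" for c in bits], dtype=bool))


@dataclass(frozen=True)
class LabeledDataset:
    """An expression matrix (N samples x M genes) with one class label per sample."""

    matrix: ExpressionMatrix
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(y) for y in self.labels)
        if len(labels) != self.matrix.n_rows:
            raise ValueError(
                f"{len(labels)} labels for {self.matrix.n_rows} samples"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def N(self) -> int:
        return self.matrix.n_rows

    @property
    def M(self) -> int:
        return self.matrix.n_cols

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))


def read_matrix(path: str | os.PathLike, delimiter: str = "\t",
                header: bool | None = None) -> ExpressionMatrix:
    """Read a delimited-text expression matrix.

    ``header=None`` auto-detects a header row (a first row whose cells are
    all non-numeric). A leading non-numeric column is taken as row ids.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    lines = [(lineno, line) for lineno, line in enumerate(raw, start=1) if line.strip()]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")

    tokenized = [(lineno, line.split(delimiter)) for lineno, line in lines]

    if header is None:
        first = tokenized[0][1]
        header = all(not _is_number(tok) for tok in first) and len(tokenized) > 1
    col_header: list[str] | None = None
    if header:
        col_header = [tok.strip() for tok in tokenized[0][1]]
        tokenized = tokenized[1:]
        if not tokenized:
            raise ParseError(f"{path}: header but no data rows")

    # Leading row-id column?
    has_row_ids = not _is_number(tokenized[0][1][0])

    width = len(tokenized[0][1])
    row_ids: list[str] = []
    body: list[list[float]] = []
    for lineno, tokens in tokenized:
        if len(tokens) != width:
            raise ParseError(f"ragged row at line {lineno}")
        if has_row_ids:
            row_ids.append(tokens[0].strip())
            tokens = tokens[1:]
        row: list[float] = []
        for j, tok in enumerate(tokens):
            if not _is_number(tok):
                rlabel = row_ids[-1] if has_row_ids else f"row {len(body) + 1}"
                raise ParseError(
                    f"non-numeric value {tok.strip()!r} at {rlabel}, column {j + 1}"
                )
            row.append(float(tok))
        body.append(row)

    n_cols = width - (1 if has_row_ids else 0)
    col_ids: tuple[str, ...] = ()
    if col_header is not None:
        if len(col_header) == n_cols + 1:
            col_header = col_header[1:]  # corner cell above the row-id column
        if len(col_header) != n_cols:
            raise ParseError(
                f"{path}: header has {len(col_header)} names for {n_cols} columns"
            )
        col_ids = tuple(col_header)
    return ExpressionMatrix(np.array(body, dtype=float),
                            row_ids=tuple(row_ids), col_ids=col_ids)


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike,
                 delimiter: str = "\t", header: bool = True,
                 row_labels: bool = True) -> None:
    """Write a matrix so that :func:`read_matrix` round-trips it exactly.

    Values are serialized with ``repr`` (shortest exact decimal form).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            cells = ([""] if row_labels else []) + list(m.col_ids)
            fh.write(delimiter.join(cells) + "\n")
        for i in range(m.n_rows):
            cells = [m.row_ids[i]] if row_labels else []
            cells += [repr(float(v)) for v in m.values[i]]
            fh.write(delimiter.join(cells) + "\n")


def read_labels(path: str | os.PathLike, delimiter: str = "\t"
                ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Read a two-column (sample_id, class) labels file."""
    ids: list[str] = []
    labels: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: expected two columns at line {lineno}, got {len(parts)}"
                )
            ids.append(parts[0])
            labels.append(parts[1])
    if not ids:
        raise ParseError(f"{path}: empty labels file")
    return tuple(ids), tuple(labels)


def write_labels(sample_ids: Sequence[str], labels: Sequence[str],
                 path: str | os.PathLike, delimiter: str = "\t") -> None:
    if len(sample_ids) != len(labels):
        raise ValueError("sample_ids and labels differ in length")
    with open(path, "w", encoding="utf-8") as fh:
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}{delimiter}{lab}\n")


def load_labeled_dataset(matrix_path: str | os.PathLike,
                         labels_path: str | os.PathLike,
                         delimiter: str = "\t") -> LabeledDataset:
    """Read matrix + labels; labels are matched to samples by id when possible,
    otherwise taken positionally."""
    matrix = read_matrix(matrix_path, delimiter=delimiter)
    ids, labels = read_labels(labels_path, delimiter=delimiter)
    if len(labels) != matrix.n_rows:
        raise ParseError(
            f"{len(labels)} labels for {matrix.n_rows} samples in {matrix_path}"
        )
    by_id = dict(zip(ids, labels))
    if set(matrix.row_ids) == set(ids):
        ordered = tuple(by_id[rid] for rid in matrix.row_ids)
    else:
        ordered = tuple(labels)
    return LabeledDataset(matrix, ordered)


def extract_submatrix(m: ExpressionMatrix, b, cols=None) -> ExpressionMatrix:
    """Extract the submatrix selected by a :class:`Bicluster`.

    Also accepts explicit index sequences ``extract_submatrix(m, rows, cols)``,
    in which case entries follow the given (possibly unsorted) order.
    """
    if isinstance(b, Bicluster):
        b.check_bounds(m.n_rows, m.n_cols)
        rows, cols = b.rows, b.cols
    else:
        rows = tuple(int(i) for i in b)
        cols = tuple(int(j) for j in cols)
        if not rows or not cols:
            raise ValueError("need at least one row and one column index")
        if max(rows) >= m.n_rows or min(rows) < 0:
            raise IndexError(f"row index out of range for {m.n_rows} rows")
        if max(cols) >= m.n_cols or min(cols) < 0:
            raise IndexError(f"column index out of range for {m.n_cols} columns")
    sub = m.values[np.ix_(rows, cols)]
    return ExpressionMatrix(
        sub,
        row_ids=tuple(m.row_ids[i] for i in rows),
        col_ids=tuple(m.col_ids[j] for j in cols),
    )
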