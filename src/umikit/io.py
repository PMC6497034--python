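"""Reading and writing the 10x-style Matrix Market triplet and sidecar tables.

Counts are stored genes-as-rows (``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``), the convention used by CellRanger output.  Batch labels
live in a sidecar ``cells.tsv`` (barcode, batch) because the triplet itself
has no slot for per-cell metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "FormatError", "read_counts", "write_counts"]


class FormatError(ValueError):
    """Raised when an on-disk matrix does not match its sidecar files."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x cells, with batch labels.

    Parameters
    ----------
    genes, cells
        Unique string identifiers for rows and columns.
    counts
        ``scipy.sparse`` matrix of shape (n_genes, n_cells) holding
        non-negative integers.
    batch
        One batch label per cell, aligned with ``cells``.
    """

    genes: pd.Index
    cells: pd.Index
    counts: sp.csr_matrix
    batch: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, dtype=object)
        self.cells = pd.Index(self.cells, dtype=object)
        if not self.genes.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell ids must be unique")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        self.batch = pd.Series(
            np.asarray(self.batch, dtype=object), index=self.cells, name="batch"
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_umi(self) -> pd.Series:
        """Total UMI count per cell."""
        return pd.Series(
            np.asarray(self.counts.sum(axis=0)).ravel(), index=self.cells, name="total_umi"
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._resolve(self.genes, mask_or_ids)
        return CountMatrix(self.genes[idx], self.cells, self.counts[idx, :], self.batch)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._resolve(self.cells, mask_or_ids)
        return CountMatrix(
            self.genes, self.cells[idx], self.counts[:, idx], self.batch.iloc[idx]
        )

    @staticmethod
    def _resolve(index: pd.Index, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.shape != (len(index),):
                raise ValueError("boolean mask has wrong length")
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":  # integer positions
            if arr.size and (arr.min() < 0 or arr.max() >= len(index)):
                raise IndexError("position out of range")
            return arr
        locs = index.get_indexer(arr)
        if (locs < 0).any():
            missing = list(np.asarray(arr)[locs < 0][:5])
            raise KeyError(f"ids not found: {missing}")
        return locs


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write a :class:`CountMatrix` as a 10x triplet plus a batch sidecar.

    Files written under ``path``: ``matrix.mtx``, ``genes.tsv`` (id and name
    columns, duplicated per 10x convention), ``barcodes.tsv`` and
    ``cells.tsv`` (barcode, batch).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(
        path / "matrix.mtx", sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape)
    )
    pd.DataFrame({"gene_id": matrix.genes, "gene_name": matrix.genes}).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": matrix.cells, "batch": matrix.batch.values}).to_csv(
        path / "cells.tsv", sep="\t", index=False
    )


def _read_mtx_header(mtx_path: Path) -> tuple[int, int, int]:
    """Parse the Matrix Market banner and size line, reporting the offending
    line number on malformed input."""
    with open(mtx_path) as fh:
        first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise FormatError(f"{mtx_path}, line 1: missing MatrixMarket banner")
        lineno = 1
        for line in fh:
            lineno += 1
            if line.startswith("%"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{mtx_path}, line {lineno}: expected 'rows cols entries', got {line.strip()!r}"
                )
            try:
                nrow, ncol, nnz = (int(p) for p in parts)
            except ValueError:
                raise FormatError(
                    f"{mtx_path}, line {lineno}: non-integer size field in {line.strip()!r}"
                ) from None
            return nrow, ncol, nnz
    raise FormatError(f"{mtx_path}, line {lineno}: no size line found")


def _read_column(path: Path, col: int) -> pd.Series:
    if path.stat().st_size == 0:
        return pd.Series([], dtype=object)
    return pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, col]


def read_counts(path: str | Path) -> CountMatrix:
    """Read a 10x triplet written by :func:`write_counts`.

    Raises
    ------
    FormatError
        If the mtx header is malformed or its dimensions disagree with
        ``genes.tsv`` / ``barcodes.tsv``.
    """
    path = Path(path)
    mtx_path = path / "matrix.mtx"
    nrow, ncol, _ = _read_mtx_header(mtx_path)
    genes = _read_column(path / "genes.tsv", 0)
    barcodes = _read_column(path / "barcodes.tsv", 0)
    if nrow != len(genes) or ncol != len(barcodes):
        raise FormatError(
            f"{mtx_path}: header declares {nrow} x {ncol} but genes.tsv has "
            f"{len(genes)} rows and barcodes.tsv has {len(barcodes)} rows"
        )
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    cells_tsv = path / "cells.tsv"
    if cells_tsv.exists():
        meta = pd.read_csv(cells_tsv, sep="\t", dtype=str)
        batch = meta.set_index("barcode")["batch"].reindex(barcodes).values
    else:
        batch = np.full(len(barcodes), "batch0", dtype=object)
    return CountMatrix(pd.Index(genes), pd.Index(barcodes), counts, pd.Series(batch))
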