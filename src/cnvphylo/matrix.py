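"""Gene-by-cell count container with CPM normalization and MTX/TSV I/O.

Counts are stored dense (genes x cells). Genomic gene coordinates, when
available, follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ExpressionMatrix", "read_counts", "cpm_normalize"]

CPM_SCALE = 1e6


class FormatError(ValueError):
    """Raised when an input file violates the expected matrix format."""


@dataclass
class ExpressionMatrix:
    """Expression values for `genes` (rows) by `cells` (columns).

    `norm_state` is "raw" (integer counts) or "cpm". `library_sizes` always
    refers to the raw per-cell totals, and survives CPM normalization.
    `gene_intervals` is an optional DataFrame indexed by gene with columns
    chrom/start/end.
    """

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    norm_state: str = "raw"
    library_sizes: Optional[np.ndarray] = None
    gene_intervals: Optional[pd.DataFrame] = None
    zero_library_cells: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            dup = self.genes[self.genes.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.genes[g]!r}, cell {self.cells[c]!r}"
            )
        if self.library_sizes is None:
            if self.norm_state != "raw":
                raise ValueError("library_sizes required for normalized matrices")
            self.library_sizes = self.values.sum(axis=0)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.zero_library_cells is None:
            self.zero_library_cells = self.library_sizes == 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        idx = self.cells.get_indexer(cells)
        if (idx < 0).any():
            missing = [c for c, i in zip(cells, idx) if i < 0]
            raise KeyError(f"unknown cells: {missing[:5]}")
        return replace(
            self,
            values=self.values[:, idx],
            cells=pd.Index(cells),
            library_sizes=self.library_sizes[idx],
            zero_library_cells=self.zero_library_cells[idx],
        )

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    def write_mtx(self, prefix: str) -> None:
        """Write matrix.mtx + genes.tsv + cells.tsv under `prefix` directory."""
        os.makedirs(prefix, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(prefix, "matrix.mtx"), scipy.sparse.coo_matrix(self.values)
        )
        pd.Series(self.genes).to_csv(
            os.path.join(prefix, "genes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(self.cells).to_csv(
            os.path.join(prefix, "cells.tsv"), sep="\t", index=False, header=False
        )


def read_counts(path: str, format: Optional[str] = None) -> ExpressionMatrix:
    """Read a raw count matrix from a wide TSV (genes x cells) or an MTX
    directory with genes.tsv/cells.tsv sidecars.

    Raises FormatError on duplicate gene IDs, ragged rows or negative counts,
    naming the offending record.
    """
    if format is None:
        format = "mtx" if os.path.isdir(path) else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:
            raise FormatError(f"ragged or unparseable TSV {path}: {exc}") from exc
        if df.isna().any().any():
            gene = df.index[df.isna().any(axis=1)][0]
            raise FormatError(f"missing value in row for gene {gene!r}")
        return ExpressionMatrix(df.to_numpy(), df.index, df.columns)
    if format == "mtx":
        m = scipy.io.mmread(os.path.join(path, "matrix.mtx")).toarray()
        genes = pd.read_csv(
            os.path.join(path, "genes.tsv"), sep="\t", header=None
        )[0]
        cells = pd.read_csv(
            os.path.join(path, "cells.tsv"), sep="\t", header=None
        )[0]
        return ExpressionMatrix(m, pd.Index(genes), pd.Index(cells))
    raise ValueError(f"unknown format {format!r}")


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to counts-per-million. Cells with zero library size are
    flagged and left all-zero. Refuses to normalize twice."""
    if m.norm_state != "raw":
        raise ValueError("matrix is already normalized")
    lib = m.library_sizes.copy()
    safe = np.where(lib > 0, lib, 1.0)
    values = m.values / safe * CPM_SCALE
    return replace(
        m,
        values=values,
        norm_state="cpm",
        library_sizes=lib,
        zero_library_cells=lib == 0,
    )
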