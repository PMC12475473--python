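"""Standard-format I/O for cell count matrices and per-cell metadata.

Counts travel as Matrix Market triplets (genes x cells, CellRanger
orientation) with ``genes.tsv`` / ``barcodes.tsv`` sidecars, or as dense
CSV. Per-cell metadata is a flat CSV. In memory, counts are held cells x
genes in a sparse :class:`CountMatrix` and metadata in a validated pandas
DataFrame (the "cell table").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("striaging")

AGE_LEVELS = ("young", "aged")

#: required cell-table columns; ``volume_um3`` and ``cluster`` are optional
CELL_TABLE_COLUMNS = ("cell_id", "x_um", "y_um", "sample_id", "age")


class SchemaError(ValueError):
    """Raised when an input table or matrix violates the expected schema."""


@dataclass
class CountMatrix:
    """Sparse cells x genes integer count matrix with identifiers.

    Attributes
    ----------
    matrix : scipy.sparse.csr_matrix
        Counts, one row per cell, one column per gene.
    cell_ids : pandas.Index
        Unique cell identifiers (row labels).
    gene_ids : pandas.Index
        Unique gene identifiers (column labels).
    """

    matrix: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.cell_ids = pd.Index(self.cell_ids, name=None).rename(None)
        self.gene_ids = pd.Index(self.gene_ids, name=None).rename(None)
        if self.matrix.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise SchemaError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not self.cell_ids.is_unique:
            raise SchemaError("cell identifiers are not unique")
        if not self.gene_ids.is_unique:
            raise SchemaError("gene identifiers are not unique")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.matrix[idx], self.cell_ids[idx], self.gene_ids)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.matrix[:, idx], self.cell_ids, self.gene_ids[idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def validate_cell_table(cells: pd.DataFrame, require_volume: bool = False) -> pd.DataFrame:
    """Check the per-cell metadata schema and return the table unchanged.

    Required columns: cell_id, x_um, y_um, sample_id, age. ``age`` must be
    'young' or 'aged'. Coordinates must be finite.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    if require_volume and "volume_um3" not in cells.columns:
        raise SchemaError("cell table missing required column: volume_um3")
    if cells["cell_id"].duplicated().any():
        raise SchemaError("cell_id values are not unique")
    bad_age = set(cells["age"].unique()) - set(AGE_LEVELS)
    if bad_age:
        raise SchemaError(f"age values outside {AGE_LEVELS}: {sorted(bad_age)}")
    for col in ("x_um", "y_um"):
        if not np.isfinite(cells[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"non-finite values in column {col}")
    return cells


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from an MTX directory/file or a dense CSV.

    MTX input follows the CellRanger layout: ``matrix.mtx`` stored genes x
    cells next to ``genes.tsv`` and ``barcodes.tsv``. A path to either the
    directory or the ``.mtx`` file is accepted. CSV input is dense with the
    first column holding identifiers; orientation is auto-detected from the
    index name (``gene``/``genes``/``gene_id`` means genes x cells,
    ``cell``/``cell_id``/``barcode`` means cells x genes; the default is
    genes x cells).
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix == ".mtx":
        return _read_mtx_dir(path.parent, mtx_name=path.name)
    if path.suffix == ".csv":
        return _read_dense_csv(path)
    raise SchemaError(f"unrecognised counts input: {path}")


def _read_mtx_dir(d: Path, mtx_name: str = "matrix.mtx") -> CountMatrix:
    mtx_path, genes_path, cells_path = d / mtx_name, d / "genes.tsv", d / "barcodes.tsv"
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise SchemaError(f"missing file: {p}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:  # mmread reports the offending line
        raise SchemaError(f"failed to parse {mtx_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0]
    if mat.shape != (len(genes), len(cells)):
        raise SchemaError(
            f"{mtx_path} is {mat.shape} but {genes_path} lists {len(genes)} genes "
            f"and {cells_path} lists {len(cells)} cells"
        )
    return CountMatrix(sp.csr_matrix(mat.T, dtype=np.int64), pd.Index(cells), pd.Index(genes))


_GENE_INDEX_NAMES = {"gene", "genes", "gene_id"}
_CELL_INDEX_NAMES = {"cell", "cells", "cell_id", "barcode"}


def _read_dense_csv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    name = (df.index.name or "").strip().lower()
    genes_by_row = name not in _CELL_INDEX_NAMES  # default: genes x cells
    if name in _GENE_INDEX_NAMES:
        genes_by_row = True
    if genes_by_row:
        df = df.T
    mat = sp.csr_matrix(df.to_numpy(dtype=np.int64))
    return CountMatrix(mat, pd.Index(df.index), pd.Index(df.columns))


def write_counts(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write counts as matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sp.coo_matrix(counts.matrix.T), field="integer")
    pd.Series(counts.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(out_dir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_cell_table(path: str | Path, require_volume: bool = False) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path), require_volume=require_volume)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Project-wide TSV convention: '.' decimal, NA for missing."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
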