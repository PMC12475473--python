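"""Platform-specific quality-control filters and log normalization.

Droplet scRNA-seq filtering keeps cells with at least ``min_genes_sc``
detected genes and mitochondrial fraction at or below ``max_mito_pct``,
then drops genes expressed in no more than ``min_cells_per_gene`` cells
(cell filter first, so gene prevalence reflects retained cells). MERFISH
filtering removes cells with fewer than ``min_genes_merfish`` detected
genes or volume below ``min_volume_um3``; no gene filter is applied for
MERFISH. Normalization is log(1 + scale_factor * x / total) with natural
log; dividing both counts and totals by cell volume cancels, so the
volume-aware MERFISH variant reduces to the same expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, SchemaError

logger = logging.getLogger("striaging")


class EmptyDatasetError(ValueError):
    """All cells or all genes were removed by filtering."""


@dataclass
class QCThresholds:
    min_genes_sc: int = 300
    min_cells_per_gene: int = 3
    max_mito_pct: float = 20.0
    min_genes_merfish: int = 10
    min_volume_um3: float = 50.0
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        vals = (self.min_genes_sc, self.min_cells_per_gene, self.max_mito_pct,
                self.min_genes_merfish, self.min_volume_um3)
        if any(v < 0 for v in vals):
            raise ValueError("QC thresholds must be nonnegative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def genes_detected_per_cell(counts: CountMatrix) -> np.ndarray:
    return np.asarray((counts.matrix > 0).sum(axis=1)).ravel()


def mito_percent(counts: CountMatrix, mito_gene_flags: np.ndarray) -> np.ndarray:
    """Percent of each cell's counts coming from flagged mitochondrial genes."""
    flags = np.asarray(mito_gene_flags, dtype=bool)
    if flags.shape != (counts.n_genes,):
        raise SchemaError("mito_gene_flags must align to genes")
    total = np.asarray(counts.matrix.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(counts.matrix[:, flags].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return pct


def filter_scrnaseq(
    counts: CountMatrix,
    mito_gene_flags: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> CountMatrix:
    """Droplet scRNA-seq cell and gene filters.

    Cells: >= ``min_genes_sc`` detected genes ('at least 300') and mito
    percent <= ``max_mito_pct`` ('above 20% removed'). Genes: expressed in
    more than ``min_cells_per_gene`` cells of the retained cells.
    """
    t = thresholds or QCThresholds()
    n_detected = genes_detected_per_cell(counts)
    pct = mito_percent(counts, mito_gene_flags)
    keep_cells = (n_detected >= t.min_genes_sc) & (pct <= t.max_mito_pct)
    if not keep_cells.any():
        raise EmptyDatasetError("no cells pass the scRNA-seq filters")
    out = counts.subset_cells(keep_cells)
    cells_per_gene = np.asarray((out.matrix > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene > t.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyDatasetError("no genes pass the prevalence filter")
    logger.info(
        "scRNA-seq QC: %d/%d cells, %d/%d genes retained",
        keep_cells.sum(), counts.n_cells, keep_genes.sum(), counts.n_genes,
    )
    return out.subset_genes(keep_genes)


def filter_merfish(
    counts: CountMatrix,
    cells: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """MERFISH cell filter: fewer than ``min_genes_merfish`` detected genes
    and/or volume strictly below ``min_volume_um3`` removes the cell."""
    t = thresholds or QCThresholds()
    if "volume_um3" not in cells.columns:
        raise SchemaError("cell table missing required column: volume_um3")
    if len(cells) != counts.n_cells:
        raise SchemaError("cell table and count matrix are not aligned")
    n_detected = genes_detected_per_cell(counts)
    volume = cells["volume_um3"].to_numpy(dtype=float)
    keep = (n_detected >= t.min_genes_merfish) & (volume >= t.min_volume_um3)
    if not keep.any():
        raise EmptyDatasetError("no cells pass the MERFISH filters")
    logger.info("MERFISH QC: %d/%d cells retained", keep.sum(), counts.n_cells)
    return counts.subset_cells(keep), cells.loc[keep].reset_index(drop=True)


def normalize_log(
    counts: CountMatrix,
    per_volume: bool = False,
    volumes: np.ndarray | None = None,
    scale_factor: float = 10_000.0,
) -> CountMatrix:
    """Total-count normalization, x10,000, natural-log transform.

    value = ln(1 + scale_factor * x_cg / T_c), T_c the cell's total counts.
    With ``per_volume``, counts and totals are first divided by cell volume,
    which cancels and leaves the result identical; the flag is validated
    and honoured for interface fidelity. All-zero cells stay all-zero.
    """
    if per_volume:
        if volumes is None:
            raise SchemaError("per_volume normalization requires volumes")
        volumes = np.asarray(volumes, dtype=float)
        if volumes.shape != (counts.n_cells,) or (volumes <= 0).any():
            raise SchemaError("volumes must be positive, one per cell")
    total = np.asarray(counts.matrix.sum(axis=1)).ravel().astype(float)
    if (total == 0).any():
        logger.warning("%d zero-total cells left all-zero", int((total == 0).sum()))
    inv = np.where(total > 0, 1.0 / np.where(total > 0, total, 1.0), 0.0)
    mat = counts.matrix.tocsr().astype(float)
    mat = sp.diags(inv) @ mat
    mat.data = np.log1p(scale_factor * mat.data)
    return CountMatrix(mat, counts.cell_ids, counts.gene_ids)
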