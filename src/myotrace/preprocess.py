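"""Cell-level QC filtering, expected-doublet-rate regression, log-normalization.

QC follows the strict boundary semantics of the thresholds as printed: cells
with *fewer than* 750 detected genes, *fewer than* 1000 transcripts, or *more
than* 30% mitochondrial transcripts are removed; equality survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .datasets import CellDataset

log = logging.getLogger(__name__)

MITO_PREFIX = "mt-"
RIBO_PREFIXES = ("Rps", "Rpl")


@dataclass(frozen=True)
class QCThresholds:
    min_features: int = 750
    min_transcripts: int = 1000
    max_mito_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.min_features < 0 or self.min_transcripts < 0:
            raise ValueError("count thresholds must be nonnegative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Removal tallies per criterion (non-exclusive) and the surviving count."""

    n_input: int
    n_kept: int
    n_low_features: int
    n_low_transcripts: int
    n_high_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "cells_in",
                    "cells_kept",
                    "removed_low_features",
                    "removed_low_transcripts",
                    "removed_high_mito",
                ],
                "value": [
                    self.n_input,
                    self.n_kept,
                    self.n_low_features,
                    self.n_low_transcripts,
                    self.n_high_mito,
                ],
            }
        )


def mito_mask(gene_meta: pd.DataFrame) -> np.ndarray:
    """``is_mito`` flag when present, otherwise the mt- name-prefix convention."""
    if "is_mito" in gene_meta.columns:
        return gene_meta["is_mito"].to_numpy(dtype=bool)
    return gene_meta["gene_id"].str.startswith(MITO_PREFIX).to_numpy()


def ribo_mask(gene_meta: pd.DataFrame) -> np.ndarray:
    if "is_ribo" in gene_meta.columns:
        return gene_meta["is_ribo"].to_numpy(dtype=bool)
    return gene_meta["gene_id"].str.startswith(RIBO_PREFIXES).to_numpy()


def filter_cells(
    ds: CellDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[CellDataset, QCReport]:
    """Keep cells with enough detected genes and transcripts and low mito load.

    A cell is kept iff detected genes >= ``min_features`` AND total counts >=
    ``min_transcripts`` AND mito fraction <= ``max_mito_fraction``. Removing
    every cell is reported as a warning, not an error.
    """
    counts = ds.counts
    detected = counts.getnnz(axis=1)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, mito_mask(ds.gene_meta)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 0.0)

    ok_feat = detected >= thresholds.min_features
    ok_tx = totals >= thresholds.min_transcripts
    ok_mito = mito_frac <= thresholds.max_mito_fraction
    keep = ok_feat & ok_tx & ok_mito
    report = QCReport(
        n_input=ds.n_cells,
        n_kept=int(keep.sum()),
        n_low_features=int((~ok_feat).sum()),
        n_low_transcripts=int((~ok_tx).sum()),
        n_high_mito=int((~ok_mito).sum()),
    )
    if report.n_kept == 0:
        log.warning("QC removed every cell (%d input)", ds.n_cells)
    return ds.subset_cells(keep), report


def estimate_doublet_rate(n_cells_after_qc: int, table) -> float:
    """Expected doublet rate at a cell count, by OLS on a published rate table.

    ``table`` is a sequence of (cells, expected_rate) pairs (or a 2-column
    DataFrame) with at least two rows, strictly increasing counts and rates in
    [0, 1]. The ordinary least-squares line through the pairs is evaluated at
    ``n_cells_after_qc`` and clamped to [0, 1]; a negative raw prediction is
    logged.
    """
    if isinstance(table, pd.DataFrame):
        pairs = table.iloc[:, :2].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(table), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("doublet-rate table needs at least two (count, rate) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("cell counts in the table must be strictly increasing")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("rates must be in [0, 1]")
    slope, intercept = np.polyfit(x, y, 1)
    raw = slope * n_cells_after_qc + intercept
    if raw < 0:
        log.warning("doublet-rate regression predicts %.4g < 0; clamping to 0", raw)
    return float(min(max(raw, 0.0), 1.0))


def log_normalize(ds_or_counts, scale_factor: float = 1e4) -> sparse.csr_matrix:
    """Seurat-style log-normalization: ln(1 + scale * count / cell_total).

    Cells with zero total counts come out as all-zero rows (logged as a
    warning). Zero counts stay exactly zero, so sparsity is preserved.
    """
    counts = ds_or_counts.counts if isinstance(ds_or_counts, CellDataset) else ds_or_counts
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    mat = sparse.csr_matrix(counts, dtype=float, copy=True)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("%d cell(s) with zero total counts produce all-zero rows", n_zero)
    row_of = np.repeat(np.arange(mat.shape[0]), np.diff(mat.indptr))
    safe = np.where(totals > 0, totals, 1.0)
    mat.data = np.log1p(scale_factor * mat.data / safe[row_of])
    return mat
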