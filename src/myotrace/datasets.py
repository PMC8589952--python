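"""In-memory containers for cell x gene and spot x gene count data, plus disk I/O.

Counts are kept as scipy CSR sparse matrices of nonnegative integers; metadata
tables are pandas DataFrames. On disk a dataset is a directory of Matrix Market
(``matrix.mtx``) plus TSV sidecars, with simulation ground truth segregated
into ``truth.tsv`` so downstream stages cannot read it by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

TRUTH_CELL_COLUMNS = ("true_stage", "true_pseudotime")


def _as_csr(m) -> sparse.csr_matrix:
    m = sparse.csr_matrix(m)
    if m.nnz and m.data.min() < 0:
        raise ValueError("counts must be nonnegative")
    return m


@dataclass
class CellDataset:
    """Sparse cell x gene raw counts with cell, gene and sample metadata.

    ``cell_meta`` carries at least ``sample_id``; simulated data adds
    ``assay_type``, ``injury_timepoint_dpi``, an observable ``embedding_axis``
    trajectory coordinate, and (ground truth) ``true_stage``/``true_pseudotime``.
    ``sample_meta`` carries ``sample_id`` and ``sequencing_saturation``.
    """

    counts: sparse.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.validate()

    # -- contract checks ---------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ValueError("cell_meta rows must equal counts rows")
        if len(self.gene_meta) != n_genes:
            raise ValueError("gene_meta rows must equal counts columns")
        known = set(self.sample_meta["sample_id"])
        missing = set(self.cell_meta["sample_id"]) - known
        if missing:
            raise ValueError(f"cell_meta sample_id not in sample_meta: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    def saturation_per_cell(self) -> np.ndarray:
        lut = self.sample_meta.set_index("sample_id")["sequencing_saturation"]
        return lut.loc[self.cell_meta["sample_id"]].to_numpy(dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "CellDataset":
        mask = np.asarray(mask)
        return CellDataset(
            counts=self.counts[mask],
            cell_meta=self.cell_meta.loc[np.asarray(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.cell_meta.iloc[mask].reset_index(drop=True),
            gene_meta=self.gene_meta,
            sample_meta=self.sample_meta,
        )


@dataclass
class SpotDataset:
    """Sparse spot x gene counts with spot coordinates and timepoint labels.

    ``true_theta`` (spots x types, rows on the simplex) is simulation ground
    truth and is written separately from the observable tables.
    """

    counts: sparse.csr_matrix
    spot_meta: pd.DataFrame
    gene_ids: np.ndarray
    true_theta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        if len(self.spot_meta) != self.counts.shape[0]:
            raise ValueError("spot_meta rows must equal counts rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids must equal counts columns")
        if self.true_theta is not None:
            rs = self.true_theta.to_numpy().sum(axis=1)
            if not np.allclose(rs, 1.0, atol=1e-9):
                raise ValueError("true_theta rows must sum to 1")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    def depths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


# ---------------------------------------------------------------------------
# Disk round-trip: MTX + TSV sidecars
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cell_dataset(ds: CellDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(ds.counts), field="integer")
    truth_cols = [c for c in TRUTH_CELL_COLUMNS if c in ds.cell_meta.columns]
    open_meta = ds.cell_meta.drop(columns=truth_cols)
    _write_tsv(open_meta, out / "cells.tsv")
    _write_tsv(ds.gene_meta, out / "genes.tsv")
    _write_tsv(ds.sample_meta, out / "samples.tsv")
    if truth_cols:
        truth = ds.cell_meta[["cell_id", *truth_cols]] if "cell_id" in ds.cell_meta else ds.cell_meta[truth_cols]
        _write_tsv(truth, out / "truth.tsv")
    return out


def read_cell_dataset(in_dir: str | Path, with_truth: bool = False) -> CellDataset:
    d = Path(in_dir)
    counts = sparse.csr_matrix(spio.mmread(d / "matrix.mtx"))
    cell_meta = pd.read_csv(d / "cells.tsv", sep="\t")
    if with_truth and (d / "truth.tsv").exists():
        truth = pd.read_csv(d / "truth.tsv", sep="\t")
        join_cols = [c for c in truth.columns if c not in TRUTH_CELL_COLUMNS]
        if "cell_id" in join_cols and "cell_id" in cell_meta.columns:
            cell_meta = cell_meta.merge(truth, on="cell_id", how="left")
        else:
            cell_meta = pd.concat([cell_meta, truth[list(TRUTH_CELL_COLUMNS)]], axis=1)
    return CellDataset(
        counts=counts,
        cell_meta=cell_meta,
        gene_meta=pd.read_csv(d / "genes.tsv", sep="\t"),
        sample_meta=pd.read_csv(d / "samples.tsv", sep="\t"),
    )


def write_spot_dataset(ds: SpotDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(ds.counts), field="integer")
    _write_tsv(ds.spot_meta, out / "spots.tsv")
    _write_tsv(pd.DataFrame({"gene_id": ds.gene_ids}), out / "genes.tsv")
    if ds.true_theta is not None:
        _write_tsv(ds.true_theta, out / "truth.tsv")
    return out


def read_spot_dataset(in_dir: str | Path, with_truth: bool = False) -> SpotDataset:
    d = Path(in_dir)
    counts = sparse.csr_matrix(spio.mmread(d / "matrix.mtx"))
    truth = None
    if with_truth and (d / "truth.tsv").exists():
        truth = pd.read_csv(d / "truth.tsv", sep="\t")
    return SpotDataset(
        counts=counts,
        spot_meta=pd.read_csv(d / "spots.tsv", sep="\t"),
        gene_ids=pd.read_csv(d / "genes.tsv", sep="\t")["gene_id"].to_numpy(),
        true_theta=truth,
    )
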