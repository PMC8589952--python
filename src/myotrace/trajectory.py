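"""Equal-width binning along a 1-D trajectory coordinate and per-bin statistics.

The coordinate is a precomputed embedding axis used as a proxy for
differentiation status. Cells are split into ``n_bins`` (default 25)
equal-width bins over the observed coordinate range; per-bin summaries cover
cell counts, Simpson diversity of sample identifiers (a batch-mixing
diagnostic), composition over a covariate such as injury timepoint, and
saturation-normalized gene-detection counts. A bin-range map relabels
myogenic cells into the four differentiation states used for deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CellDataset

UNASSIGNED = 0  # bin index for cells with a non-finite coordinate


@dataclass
class BinAssignment:
    bin_index: np.ndarray  # 1..n_bins, UNASSIGNED for non-finite coordinates
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def assign_bins(coord: np.ndarray, n_bins: int = 25) -> BinAssignment:
    """Equal-width bins spanning [min, max] of the finite coordinates.

    Bin b covers [edge_b, edge_{b+1}) except the last bin, which is closed on
    the right; a coordinate exactly on an interior edge therefore lands in the
    higher bin. Non-finite coordinates are left unassigned.
    """
    coord = np.asarray(coord, dtype=float)
    finite = np.isfinite(coord)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite coordinates")
    vmin = coord[finite].min()
    vmax = coord[finite].max()
    if vmin == vmax:
        raise ValueError("constant coordinate: bins have no width")
    edges = np.linspace(vmin, vmax, n_bins + 1)
    scaled = (coord[finite] - vmin) / (vmax - vmin)
    idx = np.minimum(np.floor(scaled * n_bins).astype(int) + 1, n_bins)
    bins = np.full(coord.shape, UNASSIGNED, dtype=int)
    bins[finite] = idx
    return BinAssignment(bin_index=bins, n_bins=n_bins, bin_edges=edges)


def simpson_diversity(labels) -> float:
    """Gini-Simpson index D = 1 - sum_i p_i^2 on a categorical vector.

    D is the probability that two draws with replacement carry different
    labels: 0 for a single class, 1 - 1/k for k balanced classes. Empty input
    is undefined and reported as NaN.
    """
    s = pd.Series(labels)
    if len(s) == 0:
        return float("nan")
    p = s.value_counts(normalize=True).to_numpy()
    return float(1.0 - (p**2).sum())


def normalized_detection(ds: CellDataset) -> np.ndarray:
    """Detected genes per cell divided by the sample's sequencing saturation."""
    sat = ds.saturation_per_cell()
    if np.any(sat <= 0):
        raise ValueError("sequencing_saturation must be positive")
    return ds.counts.getnnz(axis=1) / sat


@dataclass
class BinSummary:
    per_bin: pd.DataFrame  # bin, cell_count, sample_diversity, detection quartiles
    composition: pd.DataFrame  # bin x covariate-level fractions


def per_bin_summary(ds: CellDataset, bins: BinAssignment, covariate: str) -> BinSummary:
    """Cell counts, sample-identifier Simpson diversity, covariate composition
    and saturation-normalized detection quartiles for every bin.

    Empty bins get count 0 and NaN statistics; unassigned cells are excluded.
    """
    if covariate not in ds.cell_meta.columns:
        raise KeyError(f"covariate {covariate!r} not in cell_meta")
    assigned = bins.bin_index != UNASSIGNED
    meta = ds.cell_meta.loc[assigned].copy()
    meta["bin"] = bins.bin_index[assigned]
    meta["norm_detection"] = normalized_detection(ds)[assigned]

    all_bins = pd.RangeIndex(1, bins.n_bins + 1, name="bin")
    grp = meta.groupby("bin")
    per_bin = pd.DataFrame(
        {
            "cell_count": grp.size().reindex(all_bins, fill_value=0),
            "sample_diversity": grp["sample_id"].apply(simpson_diversity).reindex(all_bins),
            "detection_median": grp["norm_detection"].median().reindex(all_bins),
            "detection_q25": grp["norm_detection"].quantile(0.25).reindex(all_bins),
            "detection_q75": grp["norm_detection"].quantile(0.75).reindex(all_bins),
        }
    ).reset_index()
    comp = (
        meta.groupby(["bin", covariate], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(all_bins, fill_value=0)
    )
    comp = comp.div(comp.sum(axis=1).replace(0, np.nan), axis=0)
    return BinSummary(per_bin=per_bin, composition=comp)


@dataclass
class StateRelabelMap:
    """Ordered (bin_lo, bin_hi, state) ranges mapping bins to myogenic states."""

    ranges: list[tuple[int, int, str]] = field(
        default_factory=lambda: [
            (4, 5, "Quiescent MuSCs"),
            (6, 7, "Activated MuSCs"),
            (8, 10, "Committed Myoblasts"),
            (11, 18, "Fusing Myocytes"),
        ]
    )

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for lo, hi, name in self.ranges:
            if lo > hi:
                raise ValueError(f"range for {name!r} has lo > hi")
            span = set(range(lo, hi + 1))
            if span & seen:
                raise ValueError("state bin ranges overlap")
            seen |= span


DEFAULT_STATE_MAP = StateRelabelMap()


def relabel_states(
    bins: BinAssignment,
    original_labels: np.ndarray,
    state_map: StateRelabelMap = DEFAULT_STATE_MAP,
) -> np.ndarray:
    """State label per cell from its bin; bins outside all ranges keep the
    cell's original type label (so do unassigned cells)."""
    original = np.asarray(original_labels, dtype=object)
    if len(original) != len(bins.bin_index):
        raise ValueError("original_labels length must match bin assignment")
    out = original.copy()
    for lo, hi, name in state_map.ranges:
        out[(bins.bin_index >= lo) & (bins.bin_index <= hi)] = name
    return out
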