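"""Trajectory binning, Simpson diversity, per-bin summaries, state relabeling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myotrace.trajectory import (
    DEFAULT_STATE_MAP,
    StateRelabelMap,
    assign_bins,
    normalized_detection,
    per_bin_summary,
    relabel_states,
    simpson_diversity,
)

from conftest import make_cell_dataset


def test_range_endpoints_land_in_first_and_last_bin():
    ba = assign_bins(np.array([0.0, 1.0]), n_bins=25)
    assert ba.bin_index.tolist() == [1, 25]


def test_interior_edge_goes_to_higher_bin():
    # edges of 4 bins on [0,1]: 0.25 sits exactly on an interior edge
    ba = assign_bins(np.array([0.0, 0.25, 1.0]), n_bins=4)
    assert ba.bin_index[1] == 2


def test_constant_coordinate_rejected():
    with pytest.raises(ValueError):
        assign_bins(np.array([2.0, 2.0, 2.0]))


def test_nan_coordinates_unassigned_and_counts_conserved(rng):
    coord = rng.random(500)
    coord[::50] = np.nan
    ba = assign_bins(coord, n_bins=10)
    assert (ba.bin_index[::50] == 0).all()
    assert (ba.bin_index > 0).sum() == np.isfinite(coord).sum()


def test_affine_invariance_of_bins(rng):
    coord = rng.normal(size=2000)
    base = assign_bins(coord, n_bins=25).bin_index
    shifted = assign_bins(1.7 * coord - 3.2, n_bins=25).bin_index
    assert (base == shifted).all()


def test_uniform_coordinates_fill_bins_binomially(rng):
    n = 25_000
    ba = assign_bins(rng.random(n), n_bins=25)
    counts = np.bincount(ba.bin_index, minlength=26)[1:]
    # 99.9% central interval, Bonferroni-shared across the 25 bins
    lo, hi = stats.binom.interval(1 - 0.001 / 25, n, 1 / 25)
    assert counts.min() >= lo and counts.max() <= hi


# -- Simpson diversity ------------------------------------------------------

def test_simpson_closed_forms():
    assert simpson_diversity(["a"] * 10) == 0.0
    assert simpson_diversity(["a", "a", "b", "b"]) == pytest.approx(0.5)
    for k in range(1, 21):
        labels = np.repeat(np.arange(k), 30)
        assert simpson_diversity(labels) == pytest.approx(1 - 1 / k, abs=1e-12)


def test_simpson_empty_is_nan():
    assert np.isnan(simpson_diversity([]))


def test_simpson_matches_pair_sampling_estimate(rng):
    """Closed form vs brute-force probability that two draws differ."""
    labels = rng.choice(["a", "b", "c", "d"], p=[0.5, 0.3, 0.15, 0.05], size=1000)
    d = simpson_diversity(labels)
    draws_i = rng.integers(0, 1000, 200_000)
    draws_j = rng.integers(0, 1000, 200_000)
    est = (labels[draws_i] != labels[draws_j]).mean()
    assert d == pytest.approx(est, abs=0.01)


# -- per-bin summaries ------------------------------------------------------

def _summary_fixture():
    x = np.zeros((6, 4))
    x[:, 0] = [5, 5, 5, 5, 5, 5]
    x[:3, 1] = 2  # cells 0-2 detect gene 1
    ds = make_cell_dataset(
        x,
        sample_ids=["sA", "sB", "sC", "sA", "sA", "sA"],
        saturations={"sA": 0.5, "sB": 1.0, "sC": 1.0},
        dpi=[0, 0, 0, 4, 4, 7],
        coord=[0.0, 0.1, 0.2, 0.8, 0.9, 1.0],
    )
    bins = assign_bins(ds.cell_meta["coord"].to_numpy(), n_bins=2)
    return ds, bins


def test_bin_summary_counts_diversity_and_composition():
    ds, bins = _summary_fixture()
    summary = per_bin_summary(ds, bins, covariate="dpi")
    per_bin = summary.per_bin.set_index("bin")
    assert per_bin.loc[1, "cell_count"] == 3 and per_bin.loc[2, "cell_count"] == 3
    # bin 1 holds three distinct samples: D = 1 - 3*(1/3)^2 = 2/3
    assert per_bin.loc[1, "sample_diversity"] == pytest.approx(2 / 3)
    assert per_bin.loc[2, "sample_diversity"] == 0.0  # all from sA
    comp = summary.composition
    assert comp.loc[1, 0] == pytest.approx(1.0)  # bin 1 all dpi 0
    assert comp.loc[2, 4] == pytest.approx(2 / 3)
    assert comp.loc[2, 7] == pytest.approx(1 / 3)
    assert np.allclose(comp.sum(axis=1), 1.0)


def test_bin_composition_matches_brute_force_recount(small_sim):
    bins = assign_bins(small_sim.cell_meta["embedding_axis"].to_numpy(), n_bins=10)
    summary = per_bin_summary(small_sim, bins, covariate="sample_id")
    target_bin = int(pd.Series(bins.bin_index).value_counts().idxmax())
    in_bin = small_sim.cell_meta.loc[bins.bin_index == target_bin, "sample_id"]
    expected = in_bin.value_counts(normalize=True)
    for sample, frac in expected.items():
        assert summary.composition.loc[target_bin, sample] == pytest.approx(frac)


def test_empty_bins_have_zero_count_and_missing_stats():
    ds, _ = _summary_fixture()
    bins = assign_bins(ds.cell_meta["coord"].to_numpy(), n_bins=30)
    summary = per_bin_summary(ds, bins, covariate="dpi")
    empty = summary.per_bin.set_index("bin")["cell_count"] == 0
    assert empty.any()
    assert summary.per_bin.set_index("bin").loc[empty, "sample_diversity"].isna().all()


def test_unknown_covariate_rejected(small_sim):
    bins = assign_bins(small_sim.cell_meta["embedding_axis"].to_numpy())
    with pytest.raises(KeyError):
        per_bin_summary(small_sim, bins, covariate="nope")


# -- saturation-normalized detection ---------------------------------------

def test_normalized_detection_divides_by_saturation():
    x = np.zeros((2, 3000))
    x[0, :2000] = 1
    x[1, :2000] = 1
    ds = make_cell_dataset(x, sample_ids=["a", "b"], saturations={"a": 0.5, "b": 1.0})
    vals = normalized_detection(ds)
    assert vals[0] == pytest.approx(4000.0)
    assert vals[1] == pytest.approx(2000.0)  # saturation 1 -> raw count
    assert vals[0] / vals[1] == pytest.approx(2.0)


def test_nonpositive_saturation_rejected():
    ds = make_cell_dataset(np.ones((1, 3)), saturations={"s0": 0.0})
    with pytest.raises(ValueError):
        normalized_detection(ds)


# -- state relabeling -------------------------------------------------------

def test_default_state_map_ranges():
    bins = assign_bins(np.linspace(0, 1, 25), n_bins=25)  # cell i -> bin i+1
    original = np.array([f"orig{i}" for i in range(25)], dtype=object)
    states = relabel_states(bins, original)
    assert states[8] == "Committed Myoblasts"   # bin 9
    assert states[2] == "orig2"                 # bin 3 keeps its label
    assert states[17] == "Fusing Myocytes"      # bin 18
    assert states[18] == "orig18"               # bin 19 keeps its label
    assert states[3] == states[4] == "Quiescent MuSCs"
    assert states[5] == "Activated MuSCs"


def test_overlapping_ranges_rejected():
    with pytest.raises(ValueError):
        StateRelabelMap([(1, 5, "A"), (5, 8, "B")])
    with pytest.raises(ValueError):
        StateRelabelMap([(4, 2, "A")])


def test_default_map_is_valid():
    assert len(DEFAULT_STATE_MAP.ranges) == 4
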