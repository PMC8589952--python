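"""Marker discovery: vectorized rank-sum, fold-change stats, filter cascades."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from myotrace.markers import (
    GeneList,
    cross_reference,
    filter_reference_markers,
    filter_stage_markers,
    find_all_markers,
    fold_change_stats,
    rank_sum_groups,
)
from myotrace.stats import rank_sum_test


def test_vectorized_rank_sum_matches_scalar_route(rng):
    x = rng.integers(0, 6, size=(40, 15)).astype(float)
    groups = rng.integers(0, 3, 40)
    masks = np.vstack([groups == g for g in range(3)])
    u, p = rank_sum_groups(x, masks)
    for gi in range(3):
        for j in range(15):
            u_ref, p_ref = rank_sum_test(x[masks[gi], j], x[~masks[gi], j])
            assert u[gi, j] == pytest.approx(u_ref)
            assert p[gi, j] == pytest.approx(p_ref, abs=1e-12)


def test_fold_change_identical_groups_zero():
    x = np.vstack([np.tile([0.5, 1.0], (5, 1)), np.tile([0.5, 1.0], (5, 1))])
    lfc, pct_in, pct_out = fold_change_stats(x, np.arange(10) < 5)
    assert np.allclose(lfc, 0.0)
    assert np.allclose(pct_in, pct_out)


def test_fold_change_pseudocount_formula():
    # in-group unlogged mean 3, out-group 1 -> log2((3+1)/(1+1)) = 1
    x = np.zeros((4, 1))
    x[:2, 0] = np.log(4.0)  # expm1 -> 3
    x[2:, 0] = np.log(2.0)  # expm1 -> 1
    lfc, _, _ = fold_change_stats(x, np.arange(4) < 2)
    assert lfc[0] == pytest.approx(1.0)


def test_fold_change_all_zero_gene():
    lfc, pct_in, pct_out = fold_change_stats(np.zeros((6, 1)), np.arange(6) < 3)
    assert lfc[0] == 0.0 and pct_in[0] == 0.0 and pct_out[0] == 0.0


def test_perfect_separation_marker(rng):
    x = np.zeros((100, 3))
    x[:50, 0] = rng.uniform(1, 2, 50)            # only group A expresses gene 0
    x[:, 1] = rng.uniform(0.5, 1.5, 100)
    x[:, 2] = rng.uniform(0.5, 1.5, 100)
    groups = np.array(["A"] * 50 + ["B"] * 50)
    rec = find_all_markers(x, groups, ["g0", "g1", "g2"])
    top = rec.sort_values("p_adjusted").iloc[0]
    assert top["gene_id"] == "g0" and top["group"] == "A"
    assert top["pct_in"] == 1.0 and top["pct_out"] == 0.0
    assert top["avg_log2FC"] > 0


def test_single_group_rejected():
    with pytest.raises(ValueError):
        find_all_markers(np.ones((4, 2)), np.zeros(4), ["a", "b"])


def test_sparse_and_dense_inputs_agree(rng):
    x = rng.poisson(1.0, size=(30, 8)).astype(float)
    groups = rng.integers(0, 2, 30)
    a = find_all_markers(x, groups, [f"g{i}" for i in range(8)])
    b = find_all_markers(sparse.csr_matrix(x), groups, [f"g{i}" for i in range(8)])
    pd.testing.assert_frame_equal(a, b)


def test_bonferroni_monotone_and_capped(rng):
    x = rng.poisson(2.0, size=(60, 20)).astype(float)
    groups = rng.integers(0, 2, 60)
    rec = find_all_markers(x, groups, [f"g{i}" for i in range(20)])
    assert (rec["p_adjusted"] >= rec["p_value"] - 1e-15).all()
    assert (rec["p_adjusted"] <= 1.0).all()
    one = rec[rec["group"] == rec["group"].iloc[0]].sort_values("p_value")
    assert one["p_adjusted"].is_monotonic_increasing


def test_null_calibration_of_unadjusted_p(rng):
    """Randomly labeled cells: ~5% of genes reach p < 0.05."""
    x = rng.poisson(2.0, size=(400, 1000)).astype(float)
    groups = rng.integers(0, 2, 400)
    rec = find_all_markers(x, groups, [f"g{i}" for i in range(1000)])
    frac = (rec.loc[rec["group"] == 0, "p_value"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.02)


# -- cascades ---------------------------------------------------------------

def _records(rows):
    return pd.DataFrame(rows, columns=["gene_id", "group", "p_adjusted", "avg_log2FC", "pct_in"])


def test_stage_cascade_strict_boundaries():
    rec = _records([
        ("keep", 1, 1e-12, 0.6, 0.9),
        ("p_at_limit", 1, 1e-10, 0.6, 0.9),   # removed: strict '<'
        ("lfc_at_limit", 1, 1e-12, 0.5, 0.9), # removed: strict '>'
        ("both_fail", 1, 0.5, 0.0, 0.9),
    ])
    kept = filter_stage_markers(rec)
    assert kept["gene_id"].tolist() == ["keep"]
    assert filter_stage_markers(rec.iloc[0:0]).empty


def test_reference_cascade_drops_mito_ribo_and_strict_pct():
    rec = _records([
        ("good", "A", 1e-20, 1.2, 0.6),
        ("riboGene", "A", 1e-20, 2.0, 0.9),
        ("mitoGene", "B", 1e-20, 3.0, 0.9),
        ("pct_at_limit", "A", 1e-20, 2.0, 0.5),  # removed: strict '>'
        ("weak", "B", 1e-20, 0.9, 0.9),
    ])
    gene_meta = pd.DataFrame({
        "gene_id": ["good", "riboGene", "mitoGene", "pct_at_limit", "weak"],
        "is_mito": [False, False, True, False, False],
        "is_ribo": [False, True, False, False, False],
    })
    assert filter_reference_markers(rec, gene_meta) == ["good"]


def test_reference_cascade_name_prefix_fallback():
    rec = _records([("mt-Nd1", "A", 0.0, 2.0, 0.9), ("Rpl13", "A", 0.0, 2.0, 0.9),
                    ("Myog", "A", 0.0, 2.0, 0.9)])
    gene_meta = pd.DataFrame({"gene_id": ["mt-Nd1", "Rpl13", "Myog"]})
    assert filter_reference_markers(rec, gene_meta) == ["Myog"]


def test_cross_reference_intersection_and_empty_list():
    lst = GeneList(name="surface", genes={"B", "C", "D"})
    assert cross_reference({"A", "B", "C"}, lst) == {"B", "C"}
    assert cross_reference({"X"}, lst) == set()
    with pytest.raises(ValueError):
        GeneList(name="empty", genes=set())


def test_gene_list_trims_whitespace(tmp_path):
    path = tmp_path / "genes.txt"
    path.write_text("  Myog \nPax7\n\n")
    lst = GeneList.from_file(path, name="tf")
    assert lst.genes == {"Myog", "Pax7"}
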