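"""Synthetic-data generator: determinism, configured laws, ground-truth structure."""

import numpy as np
import pytest
from scipy import stats

from myotrace.simulate import (
    INTERMEDIATE_WINDOW,
    SimConfig,
    draw_pseudotime,
    generate_cells,
    generate_spots,
    random_profiles,
)
from myotrace.stats import rank_sum_test


def test_fixed_seed_reproduces_dataset_exactly():
    cfg = SimConfig(n_samples=2, cells_per_sample=100, n_genes=200, seed=42)
    a = generate_cells(cfg)
    b = generate_cells(cfg)
    assert (a.counts != b.counts).nnz == 0
    assert a.cell_meta.equals(b.cell_meta)
    assert a.sample_meta.equals(b.sample_meta)


def test_panel_overflow_rejected():
    cfg = SimConfig(n_genes=50, gene_panel_sizes={"mito": 30, "ribo": 30})
    with pytest.raises(ValueError):
        generate_cells(cfg)


@pytest.mark.parametrize("bad", [
    dict(intermediate_fraction=0.6),
    dict(saturation_range=(0.0, 0.5)),
    dict(n_samples=0),
    dict(assay_cycle=("spatial",)),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SimConfig(**bad).validate()


def test_interior_pseudotime_mass_matches_intermediate_fraction():
    # interior window holds exactly the configured mass: binomial check at
    # n=100,000 and f=0.005 against the central 99% interval around 500
    rng = np.random.default_rng(7)
    t = draw_pseudotime(rng, 100_000, 0.005)
    lo, hi = INTERMEDIATE_WINDOW
    observed = int(((t >= lo) & (t <= hi)).sum())
    lo_b, hi_b = stats.binom.interval(0.99, 100_000, 0.005)
    assert lo_b <= observed <= hi_b


def test_no_batch_effect_means_equal_across_samples():
    """With batch_effect_sd=0 and one assay type, a rank test per gene between
    two samples is non-significant at alpha=0.01 for >= 98% of genes."""
    cfg = SimConfig(n_samples=2, cells_per_sample=600, n_genes=300,
                    batch_effect_sd=0.0, assay_cycle=("cell",), seed=5)
    ds = generate_cells(cfg)
    s = ds.cell_meta["sample_id"].to_numpy()
    x = ds.counts.toarray()
    a, b = x[s == "sample00"], x[s == "sample01"]
    pvals = np.array([rank_sum_test(a[:, j], b[:, j])[1] for j in range(x.shape[1])])
    assert (pvals >= 0.01).mean() >= 0.98


def test_gene_means_converge_to_base_means():
    """One sample, no batch effects: empirical flat-gene means within 5% of the
    configured base means (genes with mean >= 1) at 50,000 cells."""
    cfg = SimConfig(n_samples=1, cells_per_sample=50_000, n_genes=150,
                    batch_effect_sd=0.0, assay_cycle=("cell",),
                    library_size_mean=1500.0, seed=11)
    ds = generate_cells(cfg)
    flat = ds.gene_meta["bump_center"].isna().to_numpy()
    base = ds.gene_meta["base_mean"].to_numpy()
    emp = np.asarray(ds.counts.mean(axis=0)).ravel()
    sel = flat & (base >= 1.0)
    assert sel.sum() > 20
    rel = np.abs(emp[sel] - base[sel]) / base[sel]
    assert rel.max() < 0.05


def test_true_stage_monotone_in_pseudotime(small_sim):
    order = np.argsort(small_sim.cell_meta["true_pseudotime"].to_numpy())
    stages = small_sim.cell_meta["true_stage"].to_numpy()[order]
    assert (np.diff(stages) >= 0).all()


def test_nucleus_assay_shifts_mito_and_lnc(small_sim):
    meta = small_sim.cell_meta
    gm = small_sim.gene_meta
    x = small_sim.counts.toarray()
    nuc = (meta["assay_type"] == "nucleus").to_numpy()
    mito = gm["is_mito"].to_numpy()
    lnc = (gm["panel"] == "lnc").to_numpy()
    assert x[nuc][:, mito].mean() < 0.5 * x[~nuc][:, mito].mean()
    assert x[nuc][:, lnc].mean() > 1.5 * x[~nuc][:, lnc].mean()


# -- spots ------------------------------------------------------------------

def test_spot_depth_exact_and_reproducible():
    prof = random_profiles(4, 60, seed=3)
    a = generate_spots(prof, 25, depth=500, dirichlet_alpha=np.ones(4), seed=9)
    b = generate_spots(prof, 25, depth=500, dirichlet_alpha=np.ones(4), seed=9)
    assert (a.depths() == 500).all()
    assert (a.counts != b.counts).nnz == 0
    assert np.allclose(a.true_theta.to_numpy().sum(axis=1), 1.0)


def test_degenerate_dirichlet_concentrates_on_one_type():
    prof = random_profiles(3, 50, seed=1)
    alpha = np.array([1e6, 1e-6, 1e-6])
    ds = generate_spots(prof, 10, depth=400, dirichlet_alpha=alpha, seed=2)
    assert np.all(ds.true_theta.iloc[:, 0] > 0.999)
    # counts restricted to type-1's expressed genes
    support = prof.mean_counts.to_numpy()[0] > 0
    outside = np.asarray(ds.counts[:, ~support].sum())
    assert outside / ds.counts.sum() < 1e-3


def test_forced_theta_split_on_disjoint_profiles():
    import pandas as pd
    from myotrace.deconv import build_profile_from_means

    means = np.zeros((2, 40))
    means[0, :20] = 5.0
    means[1, 20:] = 5.0
    prof = build_profile_from_means(
        pd.DataFrame(means, index=["t0", "t1"], columns=[f"g{i}" for i in range(40)])
    )
    # near-degenerate Dirichlet pins theta at (0.6, 0.4)
    ds = generate_spots(prof, 30, depth=10_000,
                        dirichlet_alpha=np.array([0.6e8, 0.4e8]), seed=4)
    frac_type1 = np.asarray(ds.counts[:, :20].sum(axis=1)).ravel() / 10_000
    lo, hi = stats.binom.interval(0.99, 10_000, 0.6)
    assert ((frac_type1 * 10_000 >= lo) & (frac_type1 * 10_000 <= hi)).mean() > 0.9


def test_zero_depth_rejected():
    prof = random_profiles(2, 10, seed=0)
    with pytest.raises(ValueError):
        generate_spots(prof, 5, depth=0, dirichlet_alpha=np.ones(2), seed=0)
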