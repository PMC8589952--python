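"""Synthetic multi-sample sc/snRNA-seq counts and spatial spots with ground truth.

The generator emulates the structure of a muscle-regeneration single-cell
compendium: several samples (cell or nucleus assays, different injury
timepoints, different sequencing saturations), a latent 1-D differentiation
coordinate ``t`` in [0, 1] that is dense at quiescence (t near 0) and
maturation (t near 1) and sparse in between, stage-marker genes whose mean
expression follows smooth unimodal bumps in ``t``, per-sample multiplicative
batch effects, and assay-dependent shifts for mitochondrial/ribosomal and
lncRNA-like gene panels. Spatial spots are Dirichlet-weighted multinomial
mixtures of cell-type reference profiles with the true mixing fractions
retained.

All randomness flows through one ``numpy.random.Generator`` derived from the
seed in the configuration; a fixed seed reproduces datasets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .datasets import CellDataset, SpotDataset
from .deconv import ReferenceProfile, build_profile_from_means

#: default panel sizes as fractions of n_genes (at least 2 genes each)
DEFAULT_PANEL_FRACTIONS = {
    "mito": 0.01,
    "ribo": 0.015,
    "surface": 0.04,
    "tf": 0.04,
    "stage_marker": 0.04,
    "lnc": 0.015,
}


def default_panels(n_genes: int) -> dict[str, int]:
    return {k: max(2, round(f * n_genes)) for k, f in DEFAULT_PANEL_FRACTIONS.items()}

#: interior pseudotime window that holds exactly ``intermediate_fraction`` mass
INTERMEDIATE_WINDOW = (0.3, 0.7)

_DPI_CYCLE = (0.0, 2.0, 3.5, 5.0, 7.0)


@dataclass
class SimConfig:
    """Parameters of the single-cell generator.

    Defaults are desk-scale stand-ins for a multi-sample compendium: a handful
    of samples with a few thousand cells, rare intermediate states, moderate
    batch effects, and lognormal library sizes.
    """

    n_samples: int = 6
    cells_per_sample: int = 1000
    n_genes: int = 2000
    n_bins_truth: int = 25
    intermediate_fraction: float = 0.05
    batch_effect_sd: float = 0.2
    library_size_mean: float = 8000.0
    library_size_sd: float = 0.35
    saturation_range: tuple[float, float] = (0.4, 0.9)
    gene_panel_sizes: dict[str, int] | None = None  # None scales defaults to n_genes
    seed: int = 0
    # shape of the planted stage-marker bumps (peak/baseline ratio and width in t units)
    marker_amplitude: float = 6.0
    marker_width: float = 0.05
    # assay type per sample, cycled; single-entry tuple gives a uniform assay
    assay_cycle: tuple[str, ...] = ("cell", "nucleus")

    def __post_init__(self) -> None:
        if self.gene_panel_sizes is None:
            self.gene_panel_sizes = default_panels(self.n_genes)

    def validate(self) -> None:
        for name in ("n_samples", "cells_per_sample", "n_genes", "n_bins_truth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.intermediate_fraction < 0.5:
            raise ValueError("intermediate_fraction must be in [0, 0.5)")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be nonnegative")
        lo, hi = self.saturation_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("saturation_range values must lie in (0, 1] with lo <= hi")
        if any(v < 0 for v in self.gene_panel_sizes.values()):
            raise ValueError("gene panel sizes must be nonnegative")
        if sum(self.gene_panel_sizes.values()) > self.n_genes:
            raise ValueError("sum of gene_panel_sizes exceeds n_genes")
        if not self.assay_cycle or set(self.assay_cycle) - {"cell", "nucleus"}:
            raise ValueError("assay_cycle entries must be 'cell' or 'nucleus'")


def draw_pseudotime(rng: np.random.Generator, n: int, intermediate_fraction: float) -> np.ndarray:
    """Differentiation coordinate: Beta-shaped endpoint lobes + uniform interior.

    The endpoint components live on [0, 0.3) and (0.7, 1] (scaled Beta(1, 4),
    peaked at 0 and 1 respectively) and the interior component is uniform on
    [0.3, 0.7], so the interior window carries exactly
    ``intermediate_fraction`` of the mass.
    """
    lo, hi = INTERMEDIATE_WINDOW
    comp = rng.random(n)
    t = np.empty(n)
    interior = comp < intermediate_fraction
    t[interior] = rng.uniform(lo, hi, interior.sum())
    rest = ~interior
    left = rest & (rng.random(n) < 0.5)
    right = rest & ~left
    t[left] = lo * rng.beta(1.0, 4.0, left.sum())
    t[right] = 1.0 - lo * rng.beta(1.0, 4.0, right.sum())
    return t


def _gene_table(cfg: SimConfig) -> pd.DataFrame:
    panels: list[str] = []
    names: list[str] = []
    for panel, size in cfg.gene_panel_sizes.items():
        for i in range(size):
            panels.append(panel)
            if panel == "mito":
                names.append(f"mt-Sim{i:03d}")
            elif panel == "ribo":
                names.append((f"RpsSim{i:03d}" if i % 2 == 0 else f"RplSim{i:03d}"))
            elif panel == "surface":
                names.append(f"Surf{i:03d}")
            elif panel == "tf":
                names.append(f"Tf{i:03d}")
            elif panel == "stage_marker":
                names.append(f"Stmk{i:03d}")
            elif panel == "lnc":
                names.append(f"Linc{i:03d}")
            else:
                names.append(f"{panel.capitalize()}{i:03d}")
    n_other = cfg.n_genes - len(names)
    for i in range(n_other):
        panels.append("other")
        names.append(f"Gene{i:04d}")
    gm = pd.DataFrame({"gene_id": names, "panel": panels})
    gm["is_mito"] = gm["panel"] == "mito"
    gm["is_ribo"] = gm["panel"] == "ribo"
    return gm


def generate_cells(cfg: SimConfig) -> CellDataset:
    """Draw a multi-sample cell x gene count matrix with ground truth retained.

    Counts are Poisson with lognormal per-cell size factors; gene rates are a
    product of a base mean (lognormal across genes, rescaled so base means sum
    to ``library_size_mean``), a per-sample batch multiplier
    ``exp(N(0, batch_effect_sd))``, an assay shift (nucleus samples: mito/ribo
    means x0.1, lncRNA-like panel x3), and for stage-marker genes a Gaussian
    bump in ``t`` centered on the gene's assigned stage.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_meta = _gene_table(cfg)
    n_genes = cfg.n_genes

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= cfg.library_size_mean / base.sum()
    gene_meta["base_mean"] = base

    panel = gene_meta["panel"].to_numpy()
    stage_idx = np.flatnonzero(panel == "stage_marker")
    centers = (np.arange(len(stage_idx)) + 0.5) / max(len(stage_idx), 1)
    gene_meta["bump_center"] = np.nan
    gene_meta.loc[stage_idx, "bump_center"] = centers
    # a quarter of the surface and TF panels are stage-dynamic too (real
    # surface/TF markers of commitment are discovered by cross-referencing)
    for extra_panel in ("surface", "tf"):
        idx = np.flatnonzero(panel == extra_panel)
        dyn = idx[::4]
        if len(dyn):
            gene_meta.loc[dyn, "bump_center"] = np.linspace(0.35, 0.7, len(dyn))
    stage_idx = np.flatnonzero(gene_meta["bump_center"].notna().to_numpy())
    centers = gene_meta["bump_center"].to_numpy()[stage_idx]
    n_stage = len(stage_idx)

    mito_ribo = (gene_meta["is_mito"] | gene_meta["is_ribo"]).to_numpy()
    lnc = (gene_meta["panel"] == "lnc").to_numpy()

    sample_ids = [f"sample{i:02d}" for i in range(cfg.n_samples)]
    assays = [cfg.assay_cycle[i % len(cfg.assay_cycle)] for i in range(cfg.n_samples)]
    dpis = [_DPI_CYCLE[i % len(_DPI_CYCLE)] for i in range(cfg.n_samples)]
    lo, hi = cfg.saturation_range
    saturations = rng.uniform(lo, hi, cfg.n_samples)
    sample_meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "assay_type": assays,
            "injury_timepoint_dpi": dpis,
            "sequencing_saturation": saturations,
        }
    )

    if cfg.batch_effect_sd > 0:
        batch = np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_samples, n_genes)))
    else:
        batch = np.ones((cfg.n_samples, n_genes))

    blocks = []
    metas = []
    for s in range(cfg.n_samples):
        n = cfg.cells_per_sample
        t = draw_pseudotime(rng, n, cfg.intermediate_fraction)
        size = rng.lognormal(-0.5 * cfg.library_size_sd**2, cfg.library_size_sd, n)

        rates = base * batch[s]
        if assays[s] == "nucleus":
            rates = rates.copy()
            rates[mito_ribo] *= 0.1
            rates[lnc] *= 3.0
        lam = np.outer(size, rates)
        if n_stage:
            # unimodal bump per stage-marker gene, peak amplitude relative to baseline
            d = t[:, None] - centers[None, :]
            bump = 1.0 + (cfg.marker_amplitude - 1.0) * np.exp(
                -0.5 * (d / cfg.marker_width) ** 2
            )
            lam[:, stage_idx] *= bump
        blocks.append(sparse.csr_matrix(rng.poisson(lam).astype(np.int64)))

        stage = np.minimum((t * cfg.n_bins_truth).astype(int) + 1, cfg.n_bins_truth)
        metas.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample_ids[s]}_c{i:05d}" for i in range(n)],
                    "sample_id": sample_ids[s],
                    "assay_type": assays[s],
                    "injury_timepoint_dpi": dpis[s],
                    "embedding_axis": t,
                    "true_pseudotime": t,
                    "true_stage": stage,
                }
            )
        )

    return CellDataset(
        counts=sparse.vstack(blocks, format="csr"),
        cell_meta=pd.concat(metas, ignore_index=True),
        gene_meta=gene_meta,
        sample_meta=sample_meta,
    )


def random_profiles(
    n_types: int,
    n_genes: int,
    seed: int = 0,
    expressed_fraction: float = 0.25,
    mean_scale: float = 8.0,
    gene_ids: np.ndarray | None = None,
    type_names: list[str] | None = None,
) -> ReferenceProfile:
    """Well-separated synthetic type profiles (sparse lognormal mean counts).

    Each type expresses a random ~``expressed_fraction`` subset of the genes,
    which keeps pairwise profile correlations low — convenient ground truth
    for deconvolution recovery experiments.
    """
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=np.log(mean_scale), sigma=1.0, size=(n_types, n_genes))
    support = rng.random((n_types, n_genes)) < expressed_fraction
    # guarantee every type expresses something
    for k in range(n_types):
        if not support[k].any():
            support[k, rng.integers(n_genes)] = True
    means = means * support
    if gene_ids is None:
        gene_ids = np.array([f"Gene{i:04d}" for i in range(n_genes)])
    if type_names is None:
        type_names = [f"type{k}" for k in range(n_types)]
    return build_profile_from_means(pd.DataFrame(means, index=type_names, columns=gene_ids))


def generate_spots(
    profiles: ReferenceProfile,
    n_spots: int,
    depth: int,
    dirichlet_alpha: np.ndarray,
    seed: int = 0,
    timepoints_dpi: tuple[float, ...] = (2.0, 5.0, 7.0),
) -> SpotDataset:
    """Spots as Dirichlet-weighted multinomial mixtures of the type profiles.

    theta_spot ~ Dirichlet(alpha); counts_spot ~ Multinomial(depth, theta' phi).
    The drawn theta is stored as ground truth.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive count")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    k = len(profiles.type_names)
    if len(alpha) != k:
        raise ValueError("dirichlet_alpha length must equal number of types")
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet(alpha, size=n_spots)
    probs = theta @ profiles.phi
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs])
    width = max(int(np.ceil(np.sqrt(n_spots))), 1)
    spot_meta = pd.DataFrame(
        {
            "spot_id": [f"spot{i:05d}" for i in range(n_spots)],
            "x": [i % width for i in range(n_spots)],
            "y": [i // width for i in range(n_spots)],
            "timepoint_dpi": [timepoints_dpi[i % len(timepoints_dpi)] for i in range(n_spots)],
        }
    )
    return SpotDataset(
        counts=sparse.csr_matrix(counts),
        spot_meta=spot_meta,
        gene_ids=np.asarray(profiles.gene_ids),
        true_theta=pd.DataFrame(theta, columns=profiles.type_names),
    )
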