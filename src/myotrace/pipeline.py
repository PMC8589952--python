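"""End-to-end orchestration: simulate -> QC -> bins -> markers -> reference ->
deconvolution -> co-occurrence -> ligand-receptor scoring.

A single YAML configuration drives the run; one global seed deterministically
derives per-stage seeds (via ``numpy.random.SeedSequence``), so re-running an
identical configuration reproduces byte-identical outputs. Every stage writes
TSV artifacts into the run directory and the run ends with a machine-readable
``manifest.json`` (version, seeds, parameters, row counts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import tally
from .datasets import write_cell_dataset, write_spot_dataset
from .deconv import build_profiles, deconvolve
from .lr import CATEGORIES, LRDatabase, ensemble_strengths
from .markers import (
    GeneList,
    cross_reference,
    filter_reference_markers,
    filter_stage_markers,
    find_all_markers,
)
from .preprocess import QCThresholds, estimate_doublet_rate, filter_cells, log_normalize
from .simulate import SimConfig, generate_cells, generate_spots
from .trajectory import (
    DEFAULT_STATE_MAP,
    StateRelabelMap,
    assign_bins,
    per_bin_summary,
    relabel_states,
)

log = logging.getLogger(__name__)


def _sub(dataklass, mapping: dict, where: str):
    known = {f.name for f in dataclasses.fields(dataklass)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return dataklass(**mapping)


@dataclass
class SimulateSection:
    n_samples: int = 3
    cells_per_sample: int = 500
    n_genes: int = 600
    intermediate_fraction: float = 0.2
    batch_effect_sd: float = 0.2
    library_size_mean: float = 3000.0
    library_size_sd: float = 0.35


@dataclass
class QCSection:
    min_features: int = 750
    min_transcripts: int = 1000
    max_mito_fraction: float = 0.30
    doublet_table: list = field(default_factory=list)  # [[cells, rate], ...]


@dataclass
class BinsSection:
    coord_column: str = "embedding_axis"
    n_bins: int = 25
    covariate: str = "injury_timepoint_dpi"


@dataclass
class StageMarkerSection:
    max_p_adjusted: float = 1e-10
    min_log2fc: float = 0.5


@dataclass
class ReferenceMarkerSection:
    min_log2fc: float = 1.0
    min_pct: float = 0.5


@dataclass
class DeconvSection:
    n_spots: int = 60
    depth: int = 2000
    dirichlet_alpha: float = 1.0
    tol: float = 1e-8
    max_iter: int = 500


@dataclass
class CooccurrenceSection:
    max_n: int = 10
    min_theta: float = 0.01


@dataclass
class LRSection:
    database: str | None = None  # TSV path; None builds a small demo database
    n_perm: int = 0  # 0 skips permutation p-values


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    qc: QCSection = field(default_factory=QCSection)
    bins: BinsSection = field(default_factory=BinsSection)
    stage_markers: StageMarkerSection = field(default_factory=StageMarkerSection)
    reference_markers: ReferenceMarkerSection = field(default_factory=ReferenceMarkerSection)
    deconv: DeconvSection = field(default_factory=DeconvSection)
    cooccurrence: CooccurrenceSection = field(default_factory=CooccurrenceSection)
    lr: LRSection = field(default_factory=LRSection)
    state_map: list | None = None  # [[lo, hi, name], ...]; None uses the default

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sections = {
            "simulate": SimulateSection,
            "qc": QCSection,
            "bins": BinsSection,
            "stage_markers": StageMarkerSection,
            "reference_markers": ReferenceMarkerSection,
            "deconv": DeconvSection,
            "cooccurrence": CooccurrenceSection,
            "lr": LRSection,
        }
        known = set(sections) | {"seed", "state_map"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {"seed": raw.get("seed", 0), "state_map": raw.get("state_map")}
        for name, klass in sections.items():
            kwargs[name] = _sub(klass, raw.get(name, {}) or {}, name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _demo_lr_database(gene_meta: pd.DataFrame) -> LRDatabase:
    """A small interaction table over the simulated gene panels: ligands from
    the ordinary genes, receptors from the surface panel (demo plumbing when
    no curated database is supplied)."""
    surface = gene_meta.loc[gene_meta.get("panel", "") == "surface", "gene_id"].tolist()
    other = gene_meta.loc[gene_meta.get("panel", "") == "other", "gene_id"].tolist()
    n = min(6, len(surface), len(other))
    if n == 0:
        raise ValueError("cannot build a demo LR database: no surface/other genes")
    rows = []
    for i in range(n):
        receptor = surface[i] if i % 2 == 0 else f"{surface[i]},{surface[(i + 1) % n]}"
        rows.append(
            {
                "ligand": other[i],
                "receptor": receptor,
                "pathway": f"pathway{i % 3}",
                "category": CATEGORIES[i % 3],
            }
        )
    return LRDatabase(pd.DataFrame(rows))


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory. Failures halt the run
    with the failing stage named; partial outputs are preserved."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(4)]
    manifest: dict = {
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {"simulate": seeds[0], "spots": seeds[1], "lr": seeds[2]},
        "parameters": {},
        "counts": {},
    }
    stage = "simulate"
    t0 = time.monotonic()
    try:
        sim = config.simulate
        cfg = SimConfig(
            n_samples=sim.n_samples,
            cells_per_sample=sim.cells_per_sample,
            n_genes=sim.n_genes,
            intermediate_fraction=sim.intermediate_fraction,
            batch_effect_sd=sim.batch_effect_sd,
            library_size_mean=sim.library_size_mean,
            library_size_sd=sim.library_size_sd,
            seed=seeds[0],
        )
        ds = generate_cells(cfg)
        write_cell_dataset(ds, out / "cells")
        manifest["parameters"]["simulate"] = dataclasses.asdict(sim)
        manifest["counts"]["cells_simulated"] = ds.n_cells
        manifest["counts"]["genes"] = ds.n_genes
        log.info("[%s] %d cells x %d genes (%.1fs)", stage, ds.n_cells, ds.n_genes, time.monotonic() - t0)

        stage = "qc"
        thresholds = QCThresholds(
            config.qc.min_features, config.qc.min_transcripts, config.qc.max_mito_fraction
        )
        ds_qc, report = filter_cells(ds, thresholds)
        _tsv(report.to_frame(), out / "qc_report.tsv")
        write_cell_dataset(ds_qc, out / "cells_qc")
        manifest["parameters"]["qc"] = dataclasses.asdict(config.qc)
        manifest["counts"]["cells_after_qc"] = ds_qc.n_cells
        if config.qc.doublet_table:
            rate = estimate_doublet_rate(ds_qc.n_cells, config.qc.doublet_table)
            manifest["counts"]["expected_doublet_rate"] = rate
        if ds_qc.n_cells == 0:
            raise RuntimeError("QC removed every cell; adjust thresholds for this input")

        stage = "bins"
        norm = log_normalize(ds_qc)
        coord = ds_qc.cell_meta[config.bins.coord_column].to_numpy(dtype=float)
        bins = assign_bins(coord, n_bins=config.bins.n_bins)
        summary = per_bin_summary(ds_qc, bins, covariate=config.bins.covariate)
        _tsv(
            pd.DataFrame({"cell_id": ds_qc.cell_meta["cell_id"], "bin": bins.bin_index}),
            out / "bins.tsv",
        )
        _tsv(summary.per_bin, out / "bin_summary.tsv")
        _tsv(summary.composition.reset_index(), out / "bin_composition.tsv")

        stage = "markers"
        groups = bins.bin_index
        records = find_all_markers(norm, groups, ds_qc.gene_ids)
        stage_records = filter_stage_markers(
            records, config.stage_markers.max_p_adjusted, config.stage_markers.min_log2fc
        )
        _tsv(stage_records, out / "stage_markers.tsv")
        manifest["counts"]["stage_marker_records"] = len(stage_records)
        # gene lists from the simulated panels, written then cross-referenced
        for panel, fname in (("surface", "surface_genes.txt"), ("tf", "tf_genes.txt")):
            panel_genes = ds_qc.gene_meta.loc[ds_qc.gene_meta["panel"] == panel, "gene_id"]
            (out / fname).write_text("\n".join(panel_genes) + "\n")
            hits = cross_reference(
                set(stage_records["gene_id"]), GeneList.from_file(out / fname, name=panel)
            )
            (out / f"{panel}_markers.txt").write_text("\n".join(sorted(hits)) + "\n")
            manifest["counts"][f"{panel}_stage_markers"] = len(hits)

        stage = "buildref"
        state_map = (
            StateRelabelMap([(int(a), int(b), str(c)) for a, b, c in config.state_map])
            if config.state_map
            else DEFAULT_STATE_MAP
        )
        base_labels = np.array(["Myogenic"] * ds_qc.n_cells, dtype=object)
        states = relabel_states(bins, base_labels, state_map)
        ref_records = find_all_markers(norm, states, ds_qc.gene_ids)
        ref_genes = filter_reference_markers(
            ref_records,
            ds_qc.gene_meta,
            config.reference_markers.min_log2fc,
            config.reference_markers.min_pct,
        )
        (out / "reference_genes.txt").write_text("\n".join(ref_genes) + "\n")
        manifest["counts"]["reference_genes"] = len(ref_genes)
        if not ref_genes:
            raise RuntimeError("reference marker cascade returned no genes")
        profiles = build_profiles(ds_qc.counts, states, ds_qc.gene_ids, ref_genes)
        _tsv(profiles.mean_counts.reset_index(names="cell_type"), out / "profiles.tsv")

        stage = "deconv"
        alpha = np.full(len(profiles.type_names), config.deconv.dirichlet_alpha)
        spots = generate_spots(
            profiles, config.deconv.n_spots, config.deconv.depth, alpha, seed=seeds[1]
        )
        write_spot_dataset(spots, out / "spots")
        comp = deconvolve(spots, profiles, config.deconv.max_iter, config.deconv.tol)
        _tsv(comp.theta.reset_index(names="spot_id"), out / "theta.tsv")
        manifest["counts"]["spots"] = spots.n_spots
        manifest["counts"]["deconv_converged"] = int(comp.converged.sum())

        stage = "cooccur"
        cooc = tally(
            comp.theta,
            spots.spot_meta["timepoint_dpi"],
            max_n=config.cooccurrence.max_n,
            min_theta=config.cooccurrence.min_theta,
        )
        for stratum, mat in sorted(cooc.tallies.items()):
            _tsv(mat.reset_index(names="cell_type"), out / f"cooccurrence_{stratum}.tsv")

        stage = "lr"
        db = (
            LRDatabase.from_tsv(config.lr.database)
            if config.lr.database
            else _demo_lr_database(ds_qc.gene_meta)
        )
        types = sorted(pd.unique(states))
        scores, aggregate, by_cat = ensemble_strengths(
            norm, states, ds_qc.gene_ids, db, senders=types, receivers=types
        )
        _tsv(scores, out / "lr_scores.tsv")
        _tsv(aggregate.reset_index(), out / "lr_aggregate.tsv")
        _tsv(by_cat, out / "lr_by_category.tsv")
        manifest["counts"]["lr_pairs_scored"] = len(scores)
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
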