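# myotrace

Reusable downstream analyses for multi-sample single-cell / single-nucleus
RNA-seq studies of skeletal muscle regeneration, paired with spatial
transcriptomics. Skeletal muscle repair runs through rare, short-lived
myogenic states — quiescent muscle stem cells (MuSCs) activate, commit,
and fuse into myofibers — that individual datasets sample poorly. Given a
precomputed 1-D differentiation coordinate over an integrated compendium of
cells, `myotrace` provides the analysis stages that turn such a compendium
into stage-level biology:

* **QC and preprocessing** — strict cell filtering (≥ 750 detected genes,
  ≥ 1000 transcripts, ≤ 30% mitochondrial), expected-doublet-rate linear
  regression, and log-normalization `ln(1 + 10⁴·x/total)`;
* **trajectory binning** — 25 equal-width bins along the differentiation
  axis, with per-bin cell counts, Gini–Simpson diversity of sample
  identifiers `D = 1 − Σ pᵢ²` (a batch-mixing diagnostic), composition by
  injury timepoint, and saturation-normalized genes-per-cell;
* **marker discovery** — one-vs-rest Wilcoxon rank-sum tests (mid-ranks,
  tie-corrected variance, continuity correction; exact enumeration for
  small groups), with the stage cascade (adjusted p < 10⁻¹⁰,
  avg log₂FC > 0.5) and cross-referencing against surface-protein and
  transcription-factor lists;
* **spot deconvolution** — per-type reference profiles (mean raw counts over
  a marker cascade: avg log₂FC > 1, pct > 0.5, mito/ribo removed) and
  per-spot transcript fractions θ under
  `x ~ Multinomial(N, Σₖ θₖ φₖ)`, fitted by a monotone EM;
* **co-occurrence** — within-spot tallies of the up-to-10 types with
  θ ≥ 0.01, stratified by timepoint;
* **ligand-receptor scoring** — a transparent product-of-means interaction
  strength with a permutation test;
* **a synthetic-data generator** — multi-sample counts with a rare-
  intermediate differentiation continuum, batch effects, assay contrasts,
  and spots drawn as Dirichlet-weighted multinomial mixtures with known θ —
  so every stage is testable without downloading anything.

## Worked example

The bundled demo simulates a 3-sample dataset and runs every stage:

```bash
myotrace run-all --config src/myotrace/data/demo_config.yaml --out demo_run
```

The run directory contains the simulated dataset (Matrix Market + TSV
sidecars, ground truth kept in a separate `truth.tsv`), QC report, bin
summaries, marker tables, reference profiles, spot θ estimates,
co-occurrence matrices, ligand-receptor scores, and a `manifest.json`
recording seeds, parameters and row counts:

```
cells_simulated: 1500   cells_after_qc: 1500   expected_doublet_rate: 0.012
stage_marker_records: 144   surface_stage_markers: 9   tf_stage_markers: 10
reference_genes: 51   spots: 60   lr_pairs_scored: 150
```

`bin_summary.tsv` shows the per-bin statistics — e.g. bin 1 holds 256 cells
with sample diversity 0.664 (three well-mixed samples give at most 2/3) and
a median saturation-normalized detection of ~894 genes. `stage_markers.tsv`
lists the cascade survivors; the top record (`Stmk039` in bin 25,
adjusted p ≈ 1.4·10⁻¹²⁰, log₂FC ≈ 1.93, expressed in 100% of the bin) is a
planted stage marker recovered in its own bin. `theta.tsv` holds one
simplex row per spot, e.g.
`spot00000: Committed Myoblasts 0.41, Quiescent MuSCs 0.31, Myogenic 0.19, …`.
Re-running with the same config reproduces every file byte-for-byte.

Each stage is also exposed as its own subcommand (`simulate-cells`, `qc`,
`bins`, `markers`, `buildref`, `deconv`, `cooccur`, `lr`) over the same
MTX+TSV layout, and as plain library functions (`myotrace.trajectory`,
`myotrace.markers`, `myotrace.deconv`, ...).

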