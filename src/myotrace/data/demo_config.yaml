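# One-command synthetic demonstration for `myotrace run-all`.
# Sizes are desk-scale; QC thresholds are scaled to the simulated library
# depth (the package defaults of 750/1000/0.30 suit full-depth libraries).
seed: 7
simulate:
  n_samples: 3
  cells_per_sample: 500
  n_genes: 600
  intermediate_fraction: 0.2
  batch_effect_sd: 0.2
  library_size_mean: 3000
  library_size_sd: 0.35
qc:
  min_features: 150
  min_transcripts: 500
  max_mito_fraction: 0.30
  doublet_table: [[1000, 0.008], [5000, 0.04], [10000, 0.08]]
bins:
  coord_column: embedding_axis
  n_bins: 25
  covariate: injury_timepoint_dpi
stage_markers:
  max_p_adjusted: 1.0e-10
  min_log2fc: 0.5
reference_markers:
  min_log2fc: 1.0
  min_pct: 0.5
deconv:
  n_spots: 60
  depth: 2000
  dirichlet_alpha: 1.0
  tol: 1.0e-8
  max_iter: 500
cooccurrence:
  max_n: 10
  min_theta: 0.01
lr:
  database: null
  n_perm: 0
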