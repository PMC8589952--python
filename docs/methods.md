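# Methods

This note documents the models, conventions and numerical choices behind
`myotrace`, and what the synthetic data used by the test suite does and does
not establish about real data.

## Scope and data model

The package operates on two containers. `CellDataset` holds a sparse
cells × genes matrix of raw UMI counts with three metadata tables: per-cell
(sample identifier, assay type — whole cell or nucleus — injury timepoint in
days post-injury, and a precomputed 1-D trajectory coordinate), per-gene
(identifier, mitochondrial/ribosomal flags, panel membership) and per-sample
(sequencing saturation, a fraction in (0, 1] describing how completely the
library was sequenced). `SpotDataset` holds spots × genes counts with spot
coordinates and timepoints. Computing the trajectory embedding itself, batch
correction, ambient-RNA removal and doublet calling are all upstream of this
package and out of scope; the trajectory coordinate is consumed as an input.

## Quality control

A cell is kept iff it has at least `min_features` (default 750) detected
genes, at least `min_transcripts` (default 1000) total counts, and a
mitochondrial count fraction of at most `max_mito_fraction` (default 0.30).
Boundaries are deliberately strict in the removal direction ("fewer
than"/"more than"): equality survives. "Features" means genes with count
> 0; mitochondrial genes come from the `is_mito` flag when present,
otherwise the `mt-` name prefix (ribosomal analogously: `is_ribo` or
`Rps`/`Rpl` prefixes).

The expected doublet rate is an ordinary least-squares line through a
user-supplied table of (cells loaded/recovered, expected rate) pairs — the
published instrument tables are not bundled — evaluated at the post-QC cell
count and clamped to [0, 1]. No transformation is applied before the fit;
the table is consumed as printed.

Log-normalization is fixed to `ln(1 + s·x/total)` with scale factor
`s = 1e4`, the convention of the standard single-cell workflow. One defined
transform matters because the fold-change and interaction scores below are
defined on this scale. Cells with zero totals produce all-zero rows and a
logged warning.

## Trajectory binning and per-bin statistics

Cells are split into `n_bins` (default 25) equal-width bins spanning the
observed range of the trajectory coordinate — equal width, not equal
occupancy, which is what makes the U-shaped occupancy profile of a
differentiation continuum visible. Bins are half-open `[edge_b, edge_{b+1})`
with the last bin closed; a coordinate exactly on an interior edge belongs
to the higher bin; NaN coordinates are left unassigned and excluded from
summaries. Bin assignment is invariant under increasing affine transforms of
the coordinate.

Batch mixing per bin is summarized by the Gini–Simpson index on sample
identifiers, `D = 1 − Σ p_i²` — the probability that two draws with
replacement come from different samples; 0 for a single sample and
`1 − 1/k` for k balanced samples. The variant is fixed to this "near 1 means
well mixed" orientation. Transcriptomic diversity per bin is the number of
detected genes per cell divided by its sample's sequencing saturation
(reported as median and quartiles), which removes first-order differences in
sequencing depth between samples.

Myogenic differentiation states are assigned from bin ranges: bins 4–5
Quiescent MuSCs, 6–7 Activated MuSCs, 8–10 Committed Myoblasts, 11–18 Fusing
Myocytes. Cells in bins outside all ranges (e.g. culture-shifted cells in
bins 1–3, mature myonuclei beyond 18) keep their original type labels.

## Marker discovery

Differential expression is one-vs-rest per group (bin or state) with a
Wilcoxon rank-sum test implemented from first principles: mid-ranks for
ties, normal approximation with tie-corrected variance and a 0.5 continuity
correction, and an exact enumeration of all group assignments for small
groups that serves as the reference method in the tests. When every pooled
value is tied the variance is zero and p is reported as 1. The asymptotic
path agrees with scipy's implementation to machine precision; the exact and
asymptotic p agree to ~0.01 at group sizes 8–10 without ties. Under heavy
ties at very small n the exact permutation p is a coarse step function and
no continuous approximation can track it pointwise — the test suite records
this openly rather than hiding the regime.

Average fold-change is computed on un-logged normalized means with
pseudocount 1, reported in log2:
`avg_log2FC = log2((mean_in(e^x − 1) + 1) / (mean_out(e^x − 1) + 1))`.
`pct_in`/`pct_out` are the fractions of expressing (count > 0) cells inside
and outside the group. Multiple testing is Bonferroni over the genes tested
per group (the convention of the toolkit this mirrors); Benjamini–Hochberg
is available as an option. No pre-filtering is applied before testing — the
cascades below act on the full record table.

Two cascades are provided, both with strict inequalities:

* stage markers: `p_adjusted < 1e-10` and `avg_log2FC > 0.5`; the surviving
  genes can be intersected with curated surface-protein or transcription
  factor lists (plain text, one symbol per line, whitespace-trimmed,
  case-sensitive);
* deconvolution reference genes: `avg_log2FC > 1` and `pct_in > 0.5` in at
  least one group, with mitochondrial and ribosomal genes then removed.

## Spot deconvolution

Each spot is treated as a miniature bulk mixture over the reference gene
set: counts `x ~ Multinomial(N, Σ_k θ_k φ_k)`, where `φ_k` is type k's
transcript-probability profile (the row-normalized mean raw counts of that
type over the reference genes, smoothed by adding 1e-8 of the row total to
every entry so that no gene has probability exactly zero) and `θ` is the
fraction of the spot's transcripts attributed to each type.

The maximum-likelihood `θ` is computed by EM:
`θ_k ← (1/N) Σ_g x_g θ_k φ_kg / (Σ_j θ_j φ_jg)` from a uniform start,
stopping when the relative log-likelihood change falls below `tol`
(default 1e-8) or after `max_iter` (default 1000) iterations. The update
preserves the simplex analytically and the log-likelihood is concave in `θ`
for fixed `φ`, so the iteration is monotone and needs no restarts. This is a
deliberate, documented substitution: the study this pipeline mirrors used a
Bayesian Gibbs sampler but consumed only its point estimates; the likelihood
here is the same multinomial mixture, and EM is deterministic and cheap.
Exact numerical reproduction of Gibbs-derived fractions is not claimed.
Genes absent from the profile are dropped from the spot before fitting and
the dropped count fraction is reported; a spot with zero usable counts gets
a uniform `θ` and a warning; identical profile rows (non-identifiable `θ`)
are detected and logged, with EM then returning the uniform split between
the duplicates.

## Co-occurrence and interaction scores

Per spot, the "present" types are those with `θ ≥ 0.01` (exactly 0.01
counts), ordered by descending `θ` and truncated to the top 10; ties at the
cutoff rank are broken lexicographically by type name for determinism. Every
unordered pair of present types increments a symmetric tally matrix, and
each present type its own diagonal; matrices are accumulated per timepoint
stratum and overall, and are reported both as raw counts and as fractions of
the stratum's spots (the appropriate normalization being application-
dependent).

The ligand-receptor score between a sender and receiver type is the product
of the sender's mean log-normalized ligand expression and the receiver's
mean log-normalized receptor expression, with multi-subunit receptors
contributing their minimum subunit mean. It is transparent, monotone in both
inputs, zero when either side is absent, and invariant under duplication of
cells. It is not the Hill-function/trimean model of dedicated
communication-inference tools, and pathway/ensemble aggregates are plain
sums of pair scores. Significance uses label permutations with the add-one
estimator `p = (1 + #{perm ≥ obs})/(n_perm + 1)`, which is never zero and is
uniform under the null.

## Synthetic data generator

The generator emulates the structure that the analyses depend on, at desk
scale:

* a differentiation coordinate `t ∈ [0, 1]` drawn from scaled Beta(1, 4)
  lobes on [0, 0.3) and (0.7, 1] plus a uniform interior component on
  [0.3, 0.7] whose mass is exactly `intermediate_fraction` (default 0.05) —
  dense endpoints, rare intermediates;
* counts `Poisson(u_c · rate_cg)` with lognormal per-cell size factors
  `u_c` (mean 1, log-sd `library_size_sd` = 0.35) and per-gene base rates
  drawn lognormal and rescaled to sum to `library_size_mean` (default
  8000), giving negative-binomial-like overdispersion marginally;
* per-sample batch effects `exp(N(0, batch_effect_sd))` per gene (default
  sd 0.2, log scale);
* stage-marker genes with Gaussian bumps in `t` (peak/baseline
  `marker_amplitude` = 6, width 0.05), plus a quarter of the surface and
  transcription factor panels carrying bumps centered in the
  committed/fusing region — the planted ground truth for cascade tests;
* assay contrast: nucleus samples have mitochondrial/ribosomal means ×0.1
  and a lncRNA-like panel ×3;
* per-sample sequencing saturation drawn uniformly from (0.4, 0.9).

Spots are `θ ~ Dirichlet(α)` mixtures with counts
`Multinomial(depth, θᵀφ)`; the drawn `θ` is stored as ground truth,
segregated on disk (`truth.tsv`) from the observable tables so downstream
stages cannot read it by accident. All randomness flows through a single
seeded generator, so fixed seeds reproduce datasets byte-identically.

What the generator does **not** emulate: ambient RNA, doublets, spatial
autocorrelation between spots, gene-gene correlation beyond the shared
trajectory, or realistic gene-length/GC effects. Passing tests therefore
demonstrate correctness of the algorithms under the stated models — strict
thresholds applied as specified, diversity and co-occurrence tallies exact,
EM recovering the mixing fractions that generated the data — not robustness
to every artefact of real tissue data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to make the
statistical checks sharp while staying cheap: marker-recovery experiments
use 4 samples × 4000 cells × 300 genes with `intermediate_fraction` 0.4 so
that interior bins hold ≥ 500 cells (the regime in which recall is asserted)
across 20 generator seeds; deconvolution recovery uses 200 spots, 8 types
with pairwise profile correlation < 0.5, and depth 10,000; null
calibrations use 1000 genes and 200 permutation replicates. Tolerances:
profile smoothing 1e-8 of row mass; EM relative tolerance 1e-8; simplex
checks at 1e-8; bin-edge ties resolved upward; empty bins reported as
missing rather than zero diversity.

## Known limitations

* The rank-sum normal approximation is unreliable for group sizes below ~8
  with heavy ties; the exact enumeration path should be used there.
* Bonferroni is conservative for correlated genes; switch to
  Benjamini–Hochberg when ranking breadth matters.
* The deconvolution model ignores platform effects between the single-cell
  reference and spatial counts; a poorly matched reference biases θ with no
  warning beyond the reported outside-profile count fraction.
* The interaction score has no receptor-complex stoichiometry or signaling
  weighting; it supports relative comparisons between type pairs within one
  dataset only.
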