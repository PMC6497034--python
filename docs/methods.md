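# Methods

This note documents the statistical models and procedures implemented in
umikit, the parameters that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Synthetic cohorts (`umikit.sim`)

UMI counts are drawn from a negative binomial with mean μ and dispersion θ
(variance μ + μ²/θ, default θ = 2), the standard over-dispersed model for
UMI data. Per-gene baseline means are log-uniform on `nb_mean_range`
(default 0.05–2 expected UMIs per cell, typical of shallow 10x data). Each
cell type elevates a disjoint block of `marker_genes_per_type` genes
(default 25) by `marker_fold` (default 8×), giving the mutually exclusive
marker structure that cluster-level statistics assume.

*Batch effects* are per-batch, per-gene multiplicative factors
exp(N(0, `batch_logfc_sd`)) on the mean — the simplest mechanism that
produces batch-segregated embeddings while leaving within-batch biology
intact. *Hemoglobin-high cells* (default fraction 0.0392, the observed
share of nucleated red blood cells among cord-blood cells) form their own
population with an 8-gene hemoglobin block at 50× baseline.
*Doublets* (default 3% of cells) are sums of two independent parent-type
draws, each binomially thinned to half depth — the expected profile of a
droplet splitting its sequencing budget between two cells. Doublets are
concentrated in `n_doublet_pairs` (default 2) parent pairs so they form
small hybrid clusters, as droplet doublets between abundant neighboring
clusters do, rather than a diffuse scatter.

The *trajectory* generator places `traj_n_cells` (default 667) cells
uniformly on pseudotime t ∈ [0, 1]; three gene waves (early/intermediate/
late) follow Gaussian bumps peaking at t = 0, 0.5, 1 (width 0.25, 6× peak
fold over a 0.2 floor), and all means are scaled by 1 − `libsize_decay`·t
(default 0.6), so the expected library size falls by 60% across the
trajectory — the declining RNA content of maturing erythroblasts.

*Signature sets* come in two families of four (the granzyme-B and
granzyme-K programs of NK/NKT/CTL subtypes): each set draws its size
uniformly in `program_size_range` (default [116, 144]) and contains the
family's planted shared core (defaults 31 and 22 genes) plus private genes
sampled from the remaining universe.

One integer seed feeds named substreams per stage, so identical (config,
seed) pairs are bit-identical and stages can be regenerated independently.

What the generator does **not** emulate: ambient RNA, cell-cycle or other
continuous covariates, realistic gene–gene covariance beyond the planted
blocks, barcode chemistry, or empty droplets. Tests passing on these
cohorts therefore demonstrate that each statistic recovers the structure it
is designed for under its own model assumptions — not that real data meet
those assumptions.

## Quality filtration (`umikit.qc`)

A gene is *detected* in a dataset iff it has UMI ≥ 1 in at least
`min_cells_per_gene` cells (default 30). Cell statistics are computed after
this mask, matching the published ordering. A cell is removed iff detected
genes < `min_genes` OR > `max_genes` OR mitochondrial fraction >
`max_mito`; the four dataset presets used for the cord-blood atlas
(400/2,000/8%, 400/2,000/8%, 400/3,500/6%, 400/3,000/7%) ship as
`DATASET_THRESHOLDS`. Mitochondrial genes are identified by the
case-insensitive id prefix `MT-`. The published wording ("% of detected
genes are mitochondria genes") is ambiguous between a UMI share and a
gene-count share; the UMI share is the default (`mito_mode="umi"`) because
that is the downstream-tool convention, and the gene-count share is
available as a switch. Both fractions are defined as 0 for empty cells.

Hemoglobin-high clusters are flagged when their mean hemoglobin score
(mean normalized expression over the hemoglobin genes) exceeds the
across-cluster mean by more than `z_min` (default 2) across-cluster SDs —
a reproducible stand-in for flagging by visual inspection. Trajectory
cells additionally drop any cell with mitochondrial fraction > 2.5%.

## Batch-mixing alignment score (`umikit.integration`)

Every batch is subsampled without replacement to the smallest batch's
size; kNN are exact Euclidean neighbors on the subsample, self excluded,
ties broken by cell index via a stable argsort so results are
deterministic. x̄ is the mean same-batch neighbor count and the score is
1 − (x̄ − k/N)/(k − k/N), clamped to [0, 1] (x̄ < k/N would otherwise
exceed 1). Neighbors are computed in whatever dimension the embedding has.
Subsampling is one draw per seed; `n_repeats` averages several draws.
`k_sweep` and `compare_methods` share a single subsample (and, for the
sweep, a single neighbor ordering) so values are comparable across k and
across embeddings. Populations present in only one batch can be masked
via `exclude_cells` before subsampling, since a batch-exclusive population
depresses the score for reasons that are biology, not technical artifact.

## Marker detection (`umikit.markers`)

Normalization is ln(1 + scale·count/total) with scale 10⁴. A gene is
tested for a cluster iff expressed (count > 0) in ≥ `min_pct` of the
cluster or of the rest (`min_pct_mode="either"`, the upstream-tool
semantics; `"both"` available) and |log fold change| ≥ `logfc_min`, where
the fold change is ln(mean(expm1(x))+1) in-cluster minus out-of-cluster.
Both gates default to 0.25.

The test is a two-sided Wilcoxon rank-sum. When both groups have ≤ 20
cells the p-value is exact under ties: a dynamic program over the pooled
tied-rank multiset counts, for every achievable rank sum, the number of
group assignments attaining it — equivalent to enumerating all C(n, n₁)
assignments. The two-sided p is P(|S − E S| ≥ |s_obs − E S|), the distance
definition, because the tied null can be asymmetric and the "2 × min tail"
convention is then ambiguous. Larger groups use the tie-corrected normal
approximation (no continuity correction). P-values are Bonferroni-adjusted
over the genes tested within each cluster.

Doublet-cluster flagging: a cluster is flagged iff its size is ≤
`max_frac` (default 5%, the droplet-doublet rate expected at typical 10x
loading) of all cells and its marker set has Jaccard overlap ≥
`jaccard_min` with the marker sets of ≥ 2 distinct larger clusters. Marker
sets for this comparison are the top `n_top` = 30 positive markers at
nominal p < 0.05 rather than Bonferroni-adjusted ones: candidate clusters
are small and power-limited, and capped nominal sets keep set sizes
comparable. `jaccard_min` defaults to 0.15 because an ideal half-half
doublet's markers split evenly between its two parents, bounding its
Jaccard with either parent near 1/3 even without noise, while unrelated
clusters overlap near 0; 0.15 is the midpoint of that separation.

Annotation correlates each cluster's mean expression with each bulk
reference profile (Pearson, over the shared gene universe, ≥ 3 genes
required); the best label attains the maximum r, ties broken
lexicographically. No reference table ships with the package.

## Pseudotime statistics (`umikit.trajectory`)

Concordance of two orderings is Spearman's ρ with average-rank ties. The
permutation test shuffles one ordering's values B times (default 1,000).
Because a trajectory's direction is arbitrary between inference methods,
significance is computed on |ρ|; the signed ρ is also reported. Two
p-values are returned:

- `p_empirical` = (1 + #{|null| ≥ |observed|}) / (1 + B) — recommended;
- `p_ttest` — |ρ| standardized by the null sample's mean and SD, referred
  to a two-sided Student t with B − 1 df. This is the faithful reading of
  testing "the observed coefficient's deviation from the permutation
  distribution" with a t-test; standardizing by the null mean's standard
  *error* instead would reject ~86% of true nulls (measured), since the
  error shrinks with B while the observed statistic does not.

Trend tests are Spearman's ρ of a per-cell quantity against pseudotime
with the asymptotic p-value; constant inputs return ρ = 0, p = 1 and a
degenerate-input flag.

## Signature-set statistics (`umikit.signatures`)

`venn_decompose` counts all 2^m − 1 membership regions (2 ≤ m ≤ 6). The
permutation test draws, per replicate, one random subset of the universe
per set, size-matched, without replacement within a set and independently
across sets and draws; the statistic is the full-intersection size. The
default null universe is the experiment's detected genes (any universe can
be passed). `p_ttest` follows the same standardization as the trajectory
module; `p_empirical` is one-sided in the enrichment direction. When the
null sample is constant (common with large universes, where random sets
essentially never share genes 4 ways), the t statistic diverges and the
p-value is reported as its limit: 0 when the observed value differs from
the null, 1 otherwise.

Co-expression modules: Pearson correlation across the selected cells,
zero-variance genes assigned correlation 0 and flagged, average-linkage
hierarchical clustering of distance 1 − r cut to `n_modules` (default 2,
the two mutually exclusive granzyme programs). Correlations are computed
across single cells pooled from the named subtypes — four subtype means
cannot support stable gene–gene correlation — with finer sub-modules
obtainable by re-cutting at larger `n_modules`.

## Pipeline (`umikit.pipeline`, CLI)

Stages run in the fixed order simulate → qc → markers → integration →
trajectory → signatures; enabling a stage without its upstream stage is an
error naming the missing dependency. Counts are stored genes-as-rows as a
Matrix Market triplet with a `cells.tsv` batch sidecar; all tables are
tab-separated; results are JSON. The manifest echoes the configuration,
seeds and per-stage record counts and contains no timestamps, so identical
config+seed reruns are byte-identical. The `umikit` CLI exposes each stage
as a subcommand over files.

## Problem sizes and the reference computations

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
keep every Monte-Carlo check well-powered while completing in minutes:
cohorts of 600–2,000 cells with 30–600 genes, 10–20 seeds per Monte-Carlo
claim, B = 1,000–4,000 permutation draws, 200 replicates for calibration
checks, and a 12,000-gene universe for the signature-core test (sizes in
[116, 144], planted 31-gene core, B = 1,000). The acceptance script's two
quantities — the segregated-embedding alignment score and the planted-core
intersection p-value — are recomputed from scratch at those sizes on every
run.

## Known limitations

- The generator's independence assumptions (genes independent given type,
  batch and trajectory position) make planted-structure recovery easier
  than on real data with correlated backgrounds.
- The asymptotic rank-sum branch is used for groups above 20 cells; at
  moderate sizes with extreme tie mass its p-values are approximate.
- The alignment score inherits the geometry of the input embedding;
  evaluating a poor embedding measures the embedding, not the correction.
- Doublet flagging assumes parents are present as larger clusters; a
  doublet of two rare types can evade the size-ordered parent search.
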