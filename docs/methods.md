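# Methods

This note records the models and procedures `pathmod` implements, the
conventions it fixes where several readings are defensible, and what the
synthetic fixtures do and do not establish.

## Rank-based pathway activity (fast_ucell)

The score of a pathway S (n genes) in cell j is one minus the normalized
Mann–Whitney U statistic of the pathway genes' within-cell expression
ranks: PAS_j = 1 − U_j/(n·r_max) with U_j = Σ r'_{j,i} − n(n+1)/2. Ranks
are descending with average ranks for ties; ranks above the cap r_max
are uninformative in sparse single-cell data and are truncated, entering
the formula as r_max + 1. Stored rank matrices use 0 as the truncation
sentinel so they stay sparse.

Conventions fixed here:

- **Ranks are computed over all genes of the matrix**, and the
  pathway-union submatrix is extracted afterwards. Ranking the submatrix
  first would change ranks; the contract is rank-then-subset, which also
  makes each pathway's column independent of which other pathways are
  scored.
- **Ties and zeros.** Because the matrix is nonnegative, all
  zero-expression genes of a cell form a single bottom tie group with
  average rank nnz + (n_zero + 1)/2. That value is assigned in closed
  form — an exact shortcut, not an approximation — and truncated like
  any other rank. A tie group whose average rank is ≤ r_max is stored
  whole even if it straddles the cap, so a cell may store more than
  r_max entries; truncation applies to the averaged rank, nothing else.
- **C0 cells** (every pathway gene truncated, equivalently stored rank
  sum V = 0) score exactly 0.0 rather than the analytic limit
  (n−1)/(2·r_max). The vectorized path computes V and the truncated
  count z per cell and reconstructs
  PAS = 1 − (V + (r_max+1)·z − n(n+1)/2)/(n·r_max) for the rest.
- **Validity domain.** The score is bounded in [0, 1] only while
  n ≤ r_max; larger pathways are rejected. With default r_max = 1500
  this never binds in practice.
- **Determinism.** There is no randomness anywhere in this scorer, and
  per-pathway columns are computed independently with a fixed per-cell
  summation, so the PAS matrix is bit-identical across every
  (chunk_cells, workers) configuration — asserted, not just intended.
- Scores are invariant to any strictly monotone per-cell transform of
  expression (counts vs log-normalized input give identical output).

Defaults: r_max = 1500, chunk_cells = 100 000. Worker parallelism
partitions the pathway set round-robin across threads; the rank matrix
is shared read-only.

## Control-gene scores (fast_score_genes)

PAS_j = mean expression of the signature in cell j minus the mean
expression of a bin-matched control set. Genes are binned once on the
full dataset: dataset-wide mean expression is average-ranked and the
rank scale [1, n_genes] is cut into n_bins (default 25) equal-width
intervals, so tied means always share a bin. For each signature gene,
up to ctrl_size (default 50) genes are drawn uniformly without
replacement from its bin; per-gene draws are unioned and deduplicated
into S_ref.

Conventions fixed here:

- **Controls are sampled once, globally, before any chunking.**
  Re-sampling per chunk would make results depend on the chunk
  geometry; fixing them globally is also what makes the bit-stability
  guarantee achievable.
- **The control pool excludes the signature itself** (self-subtraction
  would bias scores toward 0); a flag `allow_signature_in_ctrl`
  restores the permissive behaviour.
- **Seeding.** One master seed; each pathway gets a child seed derived
  from (master seed, pathway position in sorted-name order), so worker
  scheduling cannot perturb results.
- **Summation order.** Signature and control means accumulate strictly
  left-to-right in ascending gene-index order. Shape-dependent pairwise
  reductions would otherwise produce 1-ulp differences between chunk
  layouts, breaking exact invariance.

Unlike the rank scorer, these scores depend on dataset composition
(adding cells moves gene means, hence bins and control pools) and are
shift-invariant but scale-equivariant in the expression values.

## Pseudobulk aggregation

Cell-level PAS are averaged (arithmetic mean) per (sample, cell type)
into the long table `sample, group, feature, view, value` — features
are pathways, views are cell types. Filters:

- a (sample, view) pair needs ≥ min_cells cells;
- single-group mode: a view must survive in ≥ min_samples_per_view
  pseudobulk samples; the group column is one constant label;
- multi-group mode: group = batch (each sample must map to exactly one
  batch; anything else is a hard error). A view is retained only if, in
  *every* group, it appears in strictly more than min_fraction (default
  0.75) of that group's surviving samples *and* in at least min_samples
  (default 15) of them; a view failing anywhere is dropped everywhere.

Samples missing a retained view simply contribute no row — missingness
is carried to the factor stage, never imputed as zero at this level.

## Factor model

Per (group, view) blocks are centered per feature (missing entries
excluded from the means; offsets stored). The builtin backend assembles
the centered blocks into one samples × (view, feature) matrix across
groups, zero-fills missing entries (zero = the group mean, post
centering), and takes the top-K singular triplets: factors are
U·diag(s) split back by group, weights are V split back by view. An
`external_mofa` backend delegates the fit to a MOFA-compatible
variational trainer through a pure-data adapter when `mofapy2` is
installed; the builtin backend is the one exercised by the test suite
and must pass the same planted-recovery checks.

- **Variance explained** of factor k in block (g, v):
  100·(1 − SS(Y_gv − f_k w_k^T)/SS(Y_gv)) on centered data, missing
  entries excluded from both sums.
- **Factor retention**: a factor is kept iff its variance explained,
  summed over views, reaches min_varexp_percent (default 1%) in at
  least one group. The aggregation level is a genuine design choice;
  per-group totals with a max over groups is the reading implemented.
- **Scaling** (`integrate_factors` / `integrate_weights`): per factor
  per group (or view), divide by the column's max absolute value —
  sign-preserving, bounds values to [−1, 1], leaves identically-zero
  columns untouched, and is idempotent. Z-scoring was the main
  alternative; max-abs was chosen because it preserves the zero point
  and relative sign structure that the downstream abs-max combination
  relies on.
- No sign convention is imposed on factors; flipping a factor together
  with its weights changes neither variance explained nor any test.

K defaults to 10 and must not exceed min(n_samples − 1, feature pairs).

## Module identification and interpretation

Factor values (scaled, concatenated across groups) are tested per
condition column: 2 observed levels → two-sided Mann–Whitney U
(nonparametric) or t-test (parametric); > 2 levels → Kruskal–Wallis or
one-way ANOVA. P-values are Benjamini–Hochberg-adjusted across the
retained factors (one family per condition column); adj p < 0.05 flags
a module. The Mann–Whitney implementation uses exact enumeration for
small untied samples and the tie-corrected normal approximation
otherwise. Constant factor columns report statistic 0, p = 1 rather
than NaN. Continuous traits use Spearman (default; rank-based, in line
with the nonparametric default elsewhere) or Pearson correlation, BH
across factors.

Interpretation: `top_weight_pairs` ranks (pathway, view) pairs by
signed or absolute weight with deterministic lexicographic
tie-breaking; `combine_factor_weights` builds a view × pathway matrix
as the max of |scaled weight| over a chosen factor subset, keeps the
union of each view's top_n (default 3) pathways, and orders columns by
descending mean combined weight across views.

## Synthetic fixtures

`make_synthetic_dataset` emulates a case/control cohort: per-gene
negative-binomial baselines (gamma–Poisson, lognormal gene means,
dispersion 0.5) with count sparsity that exercises the zero-tie
truncation path; planted modules multiply the genes of chosen pathways
by an effect size (default 3) in case samples within chosen cell types
only, so both the rank-based and the mean-based scorer can see them;
batches contribute a mild per-gene multiplicative offset; pathway gene
sets are drawn disjoint. A Gaussian mode supports the control-gene
scorer's shift/scale properties. Defaults (12 samples × 3 cell types ×
20 cells, 300 genes, 8 pathways of 10 genes) keep full-pipeline tests
fast while leaving every QC path reachable.

`make_planted_pseudobulk` targets the factor stage directly: 60
samples × 4 views × 20 features, three latent factors, Gaussian noise
sd 0.5. The designated condition factor's sample scores are standard
normal plus an offset of 2 for cases; its loadings are ±[0.8, 1.2] on
six planted (feature, view) pairs distributed round-robin across views
and exactly zero elsewhere; background factors carry N(0, 0.15)
loadings everywhere. Two aspects of this design are deliberate: a
multicellular module spans cell types, so every view carries at least
one planted pair — which also matters technically, because per-view
max-abs weight scaling would otherwise inflate pure-noise loadings in
a view that the module skips; and the background loading scale keeps
nuisance covariation clearly weaker than the disease module, so the
SVD does not rotate the module into a mixture. Under these conditions
the planted module is flagged (MWU + BH) and its planted pairs are
recovered with precision ≥ 0.8 in ≥ 95% of 100 seeded replicates.

What the fixtures do *not* model: ambient RNA, doublets, per-cell depth
variation, realistic cell-type proportion imbalance, or correlated
pathway overlap. Passing tests therefore demonstrate algorithmic
correctness and the pipeline's statistical behaviour under its own
assumptions, not performance on any particular atlas.

## Numerical choices and degenerate inputs

- Exact (bitwise) equality is asserted wherever the contract promises
  it: scorer vs naive oracle, chunk/worker sweeps, seed reproduction.
  Tolerances elsewhere: 1e-9 for pseudobulk mean conservation and
  centering; analytic recovery thresholds (corr > 0.999, var. expl.
  > 99%) for noise-free planted data.
- Empty pathway collections, pathway genes absent from the matrix,
  K beyond feasible rank, all-factors-filtered, empty pseudobulk after
  QC, zero-variance traits and condition levels with fewer than two
  samples are all hard errors with named offenders; all-pathways-
  dropped overlap filtering warns and returns an empty collection.
- Zero-variance (group, view) blocks report 0% variance explained with
  a warning; identically-zero factor columns stay zero through scaling.

## Known limitations

- The builtin trainer is a least-squares factorization: no ARD
  shrinkage, no per-view noise model, orthogonal factors. On strongly
  non-orthogonal planted structure it recovers subspaces, not axes.
- Zero-filling missing (sample, view) entries after centering biases
  the SVD toward group means when missingness is heavy; the pseudobulk
  QC thresholds exist precisely to keep missingness light.
- Multi-sample statistical tests assume pseudobulk samples are
  exchangeable within condition levels; repeated measures or nested
  designs are out of scope.
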