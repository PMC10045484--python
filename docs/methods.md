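# Methods

## Scope and data model

The package operates on genes × observations expression matrices (cells for
single-cell data, samples for bulk), a cell-type annotation per single-cell
dataset, named gene sets, and clinical records `(time, event, covariates)`.
Gene identity is the bare, case-sensitive symbol string; no alias mapping is
attempted, and symbols are assumed harmonized across datasets before input.
Duplicate symbols in input files are disambiguated deterministically
(`ACTB`, `ACTB.1`, … in file order). Missing expression values are rejected
rather than imputed: none of the downstream statistics define a principled
handling for them.

## Quality control and normalization

Cells are retained when their detected-gene count (genes with count > 0)
lies in `[min_genes, max_genes]` = [300, 6500] and their mitochondrial
fraction (counts on symbols starting with `MT-`, as a share of total counts)
is at most 10%. The published exclusion rules are strict inequalities, so
the boundary values are retained; zero-total cells are excluded and counted,
never an arithmetic error.

Normalization is log1p counts-per-10k: `ln(1 + c · 10⁴ / total)`. A
variance-stabilizing regression normalization is deliberately not
re-implemented: every statistic consumed downstream — ECDF-kernel
enrichment, Spearman correlation, the Wilcoxon test — depends only on
within-gene orderings across cells, which any per-cell scaling followed by a
monotone transform preserves. The package asserts this invariance as a
property test.

## Enrichment scoring

The per-observation gene-set score is a two-step rank random-walk statistic.

**Gene-level statistic.** For gene *i* and observation *j*, `z_ij` measures
how extreme *j* is within gene *i*'s distribution across observations. The
default `ecdf` kernel is the mean-tie rank divided by *n*; it makes scores
exactly invariant to strictly increasing per-gene transforms and needs no
bandwidth. The `gaussian` kernel (`z_ij = mean_k Φ((x_ij − x_ik)/h_i)`,
`h_i = sd_i/4`, sample sd, ECDF fallback for constant genes) is provided for
fidelity to the classical formulation; it is O(p·n²) and intended for
moderate n.

**Walk.** Per observation, genes are ordered by decreasing `z`, ties broken
lexically by gene id (deterministic across platforms). With ranks
`r = 1..p` and symmetric weights `w_r = |p/2 − r|^τ` (default τ = 1), an
in-set gene adds `w_r / Σ_{in-set} w`, an out-set gene subtracts
`1/(p − |G|)`. The `maxdiff` score (default) is the maximal positive plus
the minimal negative deviation of the walk; `maxdev` is the signed deviation
of maximal magnitude. Both are bounded in [−1, 1]. Degenerate corner: when
every in-set gene of an observation sits exactly at the zero-weight middle
rank (possible only for very small sets), in-set steps fall back to equal
weights. Set genes absent from the matrix are dropped with a warning; an
empty intersection or a set covering all genes is an error.

Per-cell scoring uses all cells of a dataset as the ECDF reference
population, not per-cell-type subsets, matching how whole-dataset enrichment
runs are scored in practice.

**High/low split.** Observations are dichotomized at the median score;
observations strictly above the median are "HS", ties at the median go to
"LS". An all-identical score vector is an error, not a silent 50/50 split.

## Marker detection (Gy)

One-vs-rest per cell type, on log-normalized values. A gene is tested when
it is expressed (value > 0) in ≥ 25% of the in-type cells and its log2 fold
change — `log2((mean(expm1(in)) + 1)/(mean(expm1(out)) + 1))`, the modern
Seurat convention — exceeds 0.25. The threshold is strict (`>`) following
the stricter of the two published phrasings; a `logfc_inclusive` flag flips
it to `≥`. P-values are two-sided Wilcoxon rank-sum: exact enumeration of
rank assignments for combined sizes ≤ 12 (two-sided = doubled smaller tail,
capped at 1), otherwise the normal approximation with tie and continuity
corrections. Benjamini–Hochberg adjustment is applied per cell type across
its tested (prefiltered) genes, and markers with FDR < 0.05 are retained.
Only positive enrichment is reported. Cell types with fewer than 3 cells are
skipped with a warning. The endothelial type's retained markers form the
per-dataset gene set Gy.

BH rather than Bonferroni is used for the marker FDR: the statistical
analysis convention of the source analysis names Benjamini–Hochberg
explicitly, although the marker tool it wraps defaults to Bonferroni; the
package follows the named method.

## Correlation evidence (Gx) and consensus

Within the endothelial cells of one dataset (≥ 10 required), every gene
expressed in ≥ 10 of those cells is correlated (Spearman, mean-tie ranks,
t-approximation p with df = n − 2) with the per-cell senescence enrichment
score. The expression floor exists because rank correlations on nearly
all-zero vectors are noise; floored-out genes are excluded from the BH
denominator. Gx = {ρ > 0 and FDR < 0.05}. Gn = Gx ∩ Gy.

The consensus pools candidates across datasets: for each gene in any Gn, the
geometric mean of its ρ over the k datasets where it qualified (all positive
by construction) is computed; membership requires geometric mean > 0.2
(strict) and k ≥ `min_support`. The support default is 1 — a gene need not
qualify in every dataset — because requiring all datasets makes the
signature empty whenever one cohort lacks power; a strict all-datasets mode
is available (`--all-datasets`). Output is sorted by geometric mean
descending, ties by gene id, making derivation byte-deterministic.

## Survival stage

The Cox proportional-hazards model is maximized by Newton–Raphson with
step-halving on the Breslow tie-corrected partial likelihood (Efron
available via `cox_ties`). Convergence requires successive log-likelihoods
to differ by < 1e-9 (at most 100 iterations); any |β| exceeding 50 aborts
with a monotone-likelihood (perfect separation) diagnosis. Zero-variance
covariates are rejected by name. Fits with fewer than 10 events warn.

The risk score is the linear predictor Σ_g β_g·z_gj over signature genes,
with z the per-gene z-score across the cohort — "normalized expression" is
not otherwise pinned down, and z-scoring makes coefficients comparable
across genes; `--no-zscore` uses the input values directly. Cohorts are
split at the median risk score (ties go low). Kaplan–Meier estimation and
Harrell's C use lifelines (events precede censorings at tied times; score
ties count 0.5). The two-group log-rank statistic is computed directly as
(ΣO₁ − ΣE₁)²/ΣV with the hypergeometric variance at each distinct event
time, χ² with 1 df — and is cross-checked against lifelines in the tests.
Time units are caller-declared and never converted.

Upstream feature selection (LASSO screening, stepwise reduction) is out of
scope by design: `cox_fit` accepts any covariate list and the prognostic
runner accepts an externally supplied coefficient table.

## Synthetic data generator

The single-cell generator emulates the statistical structure the analysis
assumes, not a particular tissue. Per dataset: cell types with fixed counts
(default TEC 300, Tumor 800, CAF 200, Tcell 400, Myeloid 300), 2,000 genes,
negative-binomial counts with size r = 3 (var = μ + μ²/3, typical UMI
overdispersion) and per-cell log-normal library-size factors (σ = 0.35).
Ten `MT-` genes are sized to ~5% of counts so QC is exercised; at default
sizes fewer than 5% of cells fail QC.

Latent structure: every cell carries a pan-lineage senescence activity
g ~ U(0, 1) — senescence is not an endothelial monopoly — and for TEC the
endothelial senescence activity s equals g (zero elsewhere, and recorded as
such in the ground truth). Three gene modules sit on this:

- the **readout set** (50 genes, the stand-in for a published senescence-up
  set) responds to g in *all* cell types with mean factor `exp(effect·g)`,
  so scoring it tracks senescence without being endothelial-enriched;
- the **planted endothelial program** (40 genes) responds to s (TEC only)
  and carries a ×4 endothelial baseline shift (log2FC 2), so the true genes
  pass both Gx and Gy; 20% of the readout set is drawn from the planted
  genes, mirroring the partial overlap between a senescence readout and the
  signature derived from it;
- **decoy genes** (40) respond to g everywhere but have no endothelial
  enrichment: they enter Gx and must be removed by the Gy filter — the
  generator's direct probe of the intersection's specificity.

The continuous U(0, 1) activity (rather than a binary state) keeps both the
median split and the Spearman correlation non-degenerate. Latent effect
defaults to 1.0 (log-expression shift per unit activity); the generator's
calibration requirement — mean Spearman of planted genes against s in TEC
above 0.2 — is met with margin (≈ 0.33 at defaults). Program genes are
moderately expressed (base means log-normal around 2 counts/cell) and the
background transcriptome is drawn log-normal around 1.5 counts/cell so the
responding program stays a realistic minority of each cell's counts; an
early design with a sparse background let the program dominate the library
size, and counts-per-10k normalization then deflated the planted signal
compositionally.

What the generator does *not* emulate: batch effects (the consensus operates
per dataset, which already isolates batches), doublets, ambient RNA,
cell-type misannotation, or gene-gene correlation beyond the shared latent
factors. Passing recovery tests therefore shows the pipeline's statistics
are correct and its filters behave as specified under the assumed model —
not that real cohorts will yield a signature of any particular size.

The bulk generator draws per-sample activity a ~ N(0, 1), loads it (loading
1.0, noise sd 1.0) onto 37 signature genes of a 300-gene log-intensity
table (baseline level 8, clipped at 0), and draws exponential survival times
with hazard `0.05 · exp(0.7·a)`. Independent exponential censoring is
calibrated by solving `mean_i c/(c + λ_i) = censor_rate` (Brent root
finding) so the realized censoring fraction lands within ±0.05 of the
target (default 0.3).

## Determinism and seeds

One global seed fans out to per-stage seeds by SHA-256 hashing of
`"{seed}:{stage}"` (truncated below 2³¹), so stages can be regenerated in
isolation. The derivation and prognostic workflows themselves contain no
randomness; identical inputs and configuration produce byte-identical
output files (fixed float formatting, sorted outputs), and every output
directory embeds the exact configuration with its hash.

## Problem sizes used in validation

The validation suite runs the derivation end to end on the default
generator (6 datasets × 2,000 cells × 2,000 genes, seeds 1–5), checks
enrichment scores against a naive full-walk re-implementation on 500 random
small matrices, Spearman/BH/exact-Wilcoxon against brute-force oracles,
Gx false-discovery control over 200 permutation replicates, Cox estimates
against a golden-section likelihood maximizer on 20-record instances and
against lifelines, and log-rank type-I error over 1,000 null replicates of
100 + 100 samples. These sizes were chosen so the full suite completes in
about a minute on one core while keeping every statistical check at
non-trivial power.

## Known limitations

- The gaussian kernel is quadratic in the number of observations; use the
  (default) ECDF kernel for large datasets.
- `bh_adjust` and the log-rank test are two-group / one-dimensional by
  design; no stratified or trend variants.
- The Cox fitter targets modest covariate counts (tens, not thousands); it
  performs no regularization, and monotone-likelihood data abort rather
  than returning an arbitrarily large coefficient.
- Consensus membership weighs datasets equally regardless of cell counts;
  a gene strongly correlated in one small cohort can enter at
  `min_support = 1`, which is the documented default behavior, not a bug.
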