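# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `coexpheno`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis model

The pipeline relates eight parent-rated syndrome-scale t-scores (integers,
floored at 50) to whole-blood gene expression in a two-group, demographically
matched cohort of roughly 95–100 children.

**Preprocessing.** Raw gene counts are filtered (keep genes with CPM >= 1 in
>= 50% of samples; both thresholds configurable — no published threshold
exists for this step, so the defaults are the common practice values) and
normalized to log2(CPM + 1). Library-size normalization is the documented
stand-in for the original pipeline's normalization, whose details are not
public.

**Deconvolution.** Bulk mixing is linear in cell abundance, so deconvolution
runs on linear-scale expression: per sample, OLS of expression on the
signature columns over the shared genes; while any coefficient is negative
the most negative cell type is dropped (ties broken toward the lower column
index) and the rest refit; surviving coefficients are clamped at zero and
normalized to proportions. The elimination loop terminates in at most
(number of cell types) refits. No reference signature is bundled (published
signature matrices are licensed artifacts); a synthetic signature generator
(`benchmarks.make_signature`) serves the tests.

**Surrogate variables.** Hidden structure is estimated after protecting age,
sex, race and RIN. The number of surrogate variables comes from a
permutation (parallel-analysis) criterion: residualize expression on the
protected covariates, compare each leading singular value's
variance-explained share against within-gene permutations of the residuals,
and count leading components whose exact permutation p-value
`(1 + #{null >= obs}) / (B + 1)` is <= 0.05 (B = 50 by default; B >= 50
keeps the attainable p-values meaningfully below alpha). This
distribution-free criterion replaces asymptotic alternatives because it is
directly testable: its false-positive rate is measured in the test suite.
The SVs themselves come from an iteratively re-weighted SVD: each gene is
weighted by (1 − p_SV) · p_cov from nested-model F-tests — up-weighting genes
that track the candidate SVs and do not track the covariates — and the SVD
is recomputed on the weighted residual matrix until the largest principal
angle between successive SV subspaces is < 1e-6 (max 50 iterations;
non-convergence returns the last iterate flagged).

A caveat this package makes explicit: with strongly co-expressed biological
modules in the data, the leading residual factors are biology, not
technique. Surrogate-variable counts on such data include module factors,
and removing them before network construction removes modules. The pipeline
therefore lets the user fix `k` (the reference generator plants exactly one
batch factor, so the example configs use `k: 1`) or estimate it.

**Network.** Unsigned weighted network on Pearson correlations,
`a_ij = |cor(g_i, g_j)|^beta` (signed variant available). The soft threshold
is the smallest power whose connectivity distribution reaches scale-free
R² >= 0.8 (argmax fallback). Topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

gives the clustering dissimilarity 1 − TOM. Modules come from
average-linkage hierarchical clustering with a deliberately simplified tree
cut (the full dynamic hybrid algorithm is not reproduced):

1. static cut at 0.99 x the maximum merge height;
2. recursive branch splitting wherever the merge-height gap between a branch
   root and its taller child is >= 0.01 and at least one child has >=
   `min_module_size` (30) leaves;
3. rejection of loose branches whose mean internal dissimilarity exceeds
   `q05 + 0.94 (cut − q05)` (the conventional core-scatter factor), which
   excludes agglomerations of background genes that finish merging just
   under the cut height;
4. pruning of branches below the minimum size to label 0;
5. merging of modules whose eigengenes correlate above 0.85
   (`merge_height = 0.15`), which re-fuses over-split fragments.

Step 5 needs expression, which the dissimilarity alone cannot provide, so
`detect_modules` takes an optional `expression` argument and skips the merge
without it. Module eigengenes are the first right singular vector of the
per-gene standardized module submatrix, scaled to unit variance and
sign-aligned with the module's mean standardized expression; the proportion
of variance explained is reported. Labels are deterministic given inputs:
relabeling is by decreasing size with ties broken by detection order, and
linkage ties follow scipy's deterministic ordering. Network construction in
the pipeline runs on expression residualized against the protected
covariates and the chosen surrogate variables, so hidden factors do not
masquerade as modules; the association stage keeps those same covariates in
the regression design instead of relying on the residualization.

**Association.** T-scores are modeled directly as NB2 counts (log link); an
optional `shift_floor` subtracts the floor of 50 first, as a sensitivity
analysis. The NB2 fit alternates IRLS for the coefficients with bounded
profile maximization of the dispersion until the log-likelihood changes by
< 1e-8 (max 100 outer iterations; non-convergence is flagged, never
silently accepted). If the data are not overdispersed at the Poisson fit
and a small positive dispersion does not raise the likelihood, the
Poisson-limit fit is reported with dispersion 0. Wald standard errors use
the observed information `X' diag(mu (1 + phi y) / (1 + phi mu)^2) X`. Each
(scale, eigengene) test compares the full model (eigengene + age + sex +
race + RIN + SVs) against the nested covariate-only null; BH-FDR runs over
the whole scale x module family at once; the Nagelkerke R² increment
quantifies variance explained. Gene-level follow-up tests only the genes of
FDR-significant modules, per scale, with BH-FDR across exactly those tests.
Race enters as a binary indicator; whether eigengene should be predictor or
response is not settled by the source material — predictor-of-t-score is
implemented.

**Enrichment.** One-sided hypergeometric over-representation,
`P(X >= k)` with population = universe (all retained genes), successes =
set ∩ universe, draws = module; sets outside [5, 2000] universe members are
skipped; BH-FDR within each module's family of sets.

**Polytranscript risk scores.** Per-gene weights are NB fits of the t-score
on standardized gene expression plus covariates inside the training subset;
constant genes get weight 0, p 1. A score at threshold t is
`sum_{p_g <= t} beta_g z_ig` with z standardized by training-subset
statistics only (the threshold is inclusive so t = 1 includes every gene).
The grid {0.001, 0.01, 0.05, 0.1, 0.5, 1.0} spans the conventional
risk-score range; six tests per scale are FDR-corrected. Cross-validation is
stratified 5-fold by group, mirroring the matched design.

### Calibration of pooled cross-validated evaluation

Pooled out-of-fold predictions are not independent of the outcome in the way
a naive test assumes: sample i's outcome trains the models that score every
other fold, and each cross-fold pair (i, j) enters the pooled statistic
symmetrically (i scored by a model trained on j, and vice versa). For equal
folds this exactly doubles the null variance of the pooled association
statistic — the cross-fold covariance is n_test/n_train = 1/(k − 1), so
Var(z) = 1 + (k − 1)/(k − 1) = 2, independent of k. Per-fold evaluation does
not escape the coupling and adds small-sample bias. The evaluation therefore:

* includes fold fixed effects in the pooled NB fit (against fold-level mean
  coupling);
* reports `p = 2 Phi(−|z| / sqrt(2))` for the score coefficient;
* reports a first-order bias-corrected Nagelkerke R², converting
  `max(deviance − c, 0)` with c = 2 (the null expectation of the score's
  deviance contribution under the doubled variance; c = 1, the plain
  chi-square(1) mean, in the no-fold external-weights mode).

The correction constants are analytic, not fitted. The package's own
permutation-null test verifies the calibration: under permuted phenotypes
the FDR-significant fraction is at or below nominal and the mean maximal R²
across the threshold grid is small, while planted signals are still
recovered within a ±0.05 band of the oracle in-sample R². The corrected CV
R² is mildly conservative under signal (weights estimated on 4/5 of ~95
samples are attenuated relative to an in-sample oracle fit by ~0.03–0.06).

## The synthetic cohort generator

`generate_cohort` draws, in a fixed order from a single seeded generator:

* **Covariates.** age ~ Uniform(6, 12) years; sex, race ~ Bernoulli(0.5);
  RIN ~ Normal(8.75, 0.5) truncated to (6, 10); a balanced two-group split
  (case / typically developing); a medication-history flag for ~21% of
  cases. These match the marginals such a matched pediatric cohort reports.
* **Counts.** NB2 with log-mean = gene baseline (Normal(4, 1), mean counts
  ~55–150) + module loading x factor + batch effect + small age/sex effects
  (SD 0.05) on all genes; dispersion phi = 0.2 (a typical bulk human-cohort
  value; Var = mu + phi mu²); log-means clipped to [−10, 12] before
  exponentiation.
* **Modules.** Factors are iid standard normal per sample. Member loadings
  are random-signed |Normal(0, sd)| draws re-sampled to magnitude >=
  0.35 sd: a module label asserts membership, and below that floor a gene's
  expression carries less than the conventional minimum membership
  correlation (~0.6 against its own factor at this count noise), making the
  truth label meaningless for any method. Default: 10 modules whose sizes
  decrease linearly (largest ~4x smallest) and cover ~2/3 of the 3000 genes,
  echoing the wide module-size range of real blood networks.
* **Batch.** One standard-normal per-sample batch score with multiplicative
  log-scale coefficients Normal(0, 0.5) on a random 30% of genes — partial
  affectedness is what makes surrogate-variable estimation nontrivial.
* **Cell proportions.** Dirichlet(2, ..., 2) rows, recorded as truth for the
  mixture fixture (`generate_mixture`: signature x proportions + Gaussian
  noise, clipped at 0). They do not enter the count model; deconvolution is
  exercised on explicit mixtures.
* **Phenotypes.** Each scale is
  `max(50, round(50 + 10 [softplus(lin) − log 2]))` with lin = planted
  module effects + standardized covariate effects + Normal(0, 2) noise. The
  shifted softplus is smooth, asymptotically linear and exactly zero at
  zero, so a null cohort sits exactly at the floor; the amplitude of 10
  points per unit and noise SD 2 put generated scores in the instrument's
  realistic range for an enriched cohort (span ~50–90, SD ~8–10) and make
  them overdispersed (variance > mean), as real checklist scores are — a
  requirement for the NB Wald test to be calibrated. Default effects:
  attention problems <- module 1 with effect 1.2, which yields an oracle
  in-sample Nagelkerke R² of ~0.15 at n = 95 (measured by simulation of the
  NB fit on the true factor); moderate effects on social problems, thought
  problems and aggression; four scales null.

What the generator does **not** emulate: the inter-scale correlation
structure of real checklist ratings beyond shared module effects; cell-type
composition effects inside the count model; count-level technical artifacts
(GC, length, batch-specific library chemistry); gene-gene correlation beyond
the single-factor-per-module structure; and any real gene identity or
annotation. Passing tests therefore demonstrate that each stage recovers the
structure it is designed for at realistic signal-to-noise — not that the
pipeline's findings on any real cohort are correct.

## Numerical and design details

* Dispersion is profiled on a log grid in [1e-8, 10] by bounded scalar
  minimization (xatol 1e-10); estimates <= 1e-6 collapse to the Poisson
  limit.
* Degenerate inputs: constant genes are an error in network construction
  and eigengene computation, a flagged (0, 1) weight in PTRS training, and a
  NaN-statistic record in proportion-difference testing. An empty
  low-abundance filter result warns rather than errors. Empty score
  selections yield all-zero scores with a flag.
* BH-FDR is the standard step-up (via statsmodels), validated against a
  hand step-up oracle in the tests; adjusted values never fall below the
  raw p.
* Tie-breaks: deconvolution elimination drops the lowest column index among
  equally negative coefficients; module relabeling orders by decreasing
  size then first-detection order.
* Pipeline seeding: one run seed fans out to per-stage seeds through a
  fixed counter scheme (`SeedSequence(seed)` state, reduced mod 2^31), so a
  stage re-run in isolation reproduces its in-pipeline behavior.
* Experiment sizes in `coexpheno.benchmarks` (3000-gene reference cohorts
  for module recovery, 1000-gene batch-only cohorts for SVA, 200–300-gene
  cohorts for calibration and PTRS experiments, 500 simulations for the
  type-I rate) are chosen so the full suite completes in minutes on one CPU
  while keeping every planted structure at its stated strength.

## Known limitations

* The tree cut is a documented simplification of the dynamic hybrid
  algorithm; its acceptance surface is truth-recovery on planted modules,
  not equivalence with any published implementation.
* Module counts and sizes on real data depend on parameters (power, cut
  heights, minimum size) that are configurable but were tuned only against
  the synthetic reference scenario.
* The surrogate-variable weighting function is a documented interpretation
  (affected-by-SV x unaffected-by-covariates from nested F-tests), not a
  numerical replica of any specific published implementation.
* NB Wald p-values are asymptotic; at n ~ 95 the measured type-I rate is
  close to nominal for the generator's phenotype distribution, but heavily
  floored outcomes with little dispersion make the test conservative.
* External-weights mode assumes weight tables share the expression matrix's
  gene identifiers; no identifier mapping is provided.
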