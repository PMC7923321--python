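# Methods

## Problem and setting

`drugsig` derives a small gene-expression signature predictive of a drug's
cell-line sensitivity from two inputs: a genes × cell-lines log2 expression
matrix (the CellMinerCDB tab-separated export dialect) and a per-line IC50
table in Molar units with tumor-type and lineage labels. The regression
target throughout is −log10(Molar IC50) — higher values mean a lower
inhibitory concentration, i.e. a more sensitive line. Predictions are
converted back to linear Molar scale only where a metric requires it (fold
accuracy). Working on one canonical scale avoids repeated, error-prone
log/linear conversions.

The intended regime is a small screen: ~50 training lines, tens of
thousands of genes, one biologically dominant driver gene (for acylfulvene
prodrugs such as LP-184, the reductive activator PTGR1), and an independent
blind cohort of ~40 lines for validation.

## Signature derivation funnel

1. **Preprocessing.** Samples are matched between expression and IC50
   tables by exact name (after whitespace trimming); a configured lineage
   (default `blood`, uniformly resistant in this drug class) is excluded
   before any modeling.
2. **Correlation screen.** Per-gene Pearson r against −log10(IC50); the
   two-sided p comes from the t transform `t = r·√((n−2)/(1−r²))` on n−2
   degrees of freedom. Genes with p ≤ 0.05 are kept, both signs.
   Constant-expression genes are excluded and logged. p-values below the
   smallest positive double are floored there rather than reported as 0.
3. **Biological filters (optional).** With a GMT gene-set collection and a
   list of drug-target genes, the pathway filter keeps screened genes that
   share at least one set with a target gene. With a SIF interaction
   network, the network filter adds the direct neighbors of screened genes
   (restricted to measured genes). The two retained sets are combined by
   union by default — the permissive reading; an intersection switch
   exists. Both filters are skippable so the funnel runs without curated
   resources.
4. **RReliefF ranking.** Relief is defined for classification; the
   continuous IC50 target requires the regression variant (RReliefF).
   Implementation: features and target min-max scaled, Manhattan instance
   distance, k = 10 nearest neighbors with uniform neighbor weights, and
   every sample used once as pivot, which makes the ranking fully
   deterministic. Weights contrast P(feature differs | target differs)
   with P(feature differs | target similar). The top 100 genes proceed.
5. **Boruta confirmation.** Classic shadow scheme with a random forest
   (impurity importances, `max_features = 1/3`, 100 trees): each round
   appends a permuted copy of every active feature; a feature scores a hit
   when it beats the best shadow. From round 5 a two-sided binomial test at
   α = 0.05 with Bonferroni correction across all candidates confirms or
   rejects; rejected features leave the matrix; undecided features at the
   iteration cap (default 50) are tentative and are excluded from the
   signature (conservative choice). If fewer than two genes are confirmed,
   the funnel tops up with the best-ranked tentative genes to two so the
   elimination stage has a valid input; this degenerate path is logged.
6. **Backward elimination.** A single seeded split of the training cohort
   into internal-train/holdout (default sizes 41/11, stratified by tumor
   type when feasible). Genes leave one at a time in inverse Relief-rank
   order (a model-importance order is available by config). At each set
   size the ensemble is tuned by 5×10-fold repeated cross-validated RMSE on
   internal-train over a two-point capacity grid, refit, and scored on the
   holdout by the sum of its two-fold and four-fold IC50 accuracies. The
   gene set maximizing that sum wins; ties prefer the smaller set. By
   default the criterion uses the holdout; a config switch scores pooled
   out-of-fold CV predictions instead. The elimination returns the
   internal-train model (so the trace is exactly reproducible); the
   pipeline then refits the chosen genes and hyperparameters on the full
   training cohort for deployment.

## Regression engine

The ensemble is gradient-boosted **stumps with linear leaf models**
(LightGBM `linear_tree`): 300 rounds, learning rate 0.1, depth 1, minimum
leaf size 20 (tuned over {10, 20} by CV). Rationale: on ~50 samples whose
−log10(IC50) spans several decades, conventional piecewise-constant leaves
quantize the response so coarsely that predictions systematically miss the
two-/four-fold tolerance even when the correct genes are in the model;
linear leaf models interpolate along the expression–sensitivity trend while
keeping tree semantics — split-gain variable importances and automatic
interaction handling. The minimum leaf size is the stability knob that
matters at this cohort size: leaf-level regressions on fewer than ~10 lines
overfit their leaf. Inside Boruta a plain random forest is used (the
shadow test needs importance ranking, not calibrated predictions).
Variable importances reported for a signature are split-gain importances
normalized to sum to 1.

## Evaluation

- **Fold accuracy**: fraction of lines with `max(pred, actual) /
  min(pred, actual) ≤ k` on the Molar scale, k ∈ {2, 4}; the boundary is
  inclusive ("within k-fold"), implemented with a 1e-9 relative slack so
  exactly-k ratios are not lost to floating-point rounding. The metric is
  symmetric and invariant to a common rescaling of both vectors.
- **Agreement**: Pearson r with its t-based p, and RMSE, both on
  −log10(Molar).
- **Responder classification**: z-scores of predicted −log10(IC50) within
  the prediction cohort; z > 0 is called sensitive, z ≤ 0 resistant (the
  tie goes to resistant). Zero-variance cohorts are rejected rather than
  silently scored; the zero test uses a relative tolerance because
  identical predictions can differ from their own mean by one ulp.
- **Tumor-type classification**: a type is sensitive (resistant) when
  strictly more than 60% of its lines are predicted sensitive (resistant),
  otherwise mixed; unlabeled lines are excluded and counted.

## Downstream analyses

Hierarchical co-clustering uses Euclidean distance with complete linkage;
two-way cuts are scored against known labels by the best label-to-cluster
assignment, so the agreement fraction is label-permutation invariant.
Wilcoxon rank-sum tests use full-enumeration exact p for groups of ≤ 10
without ties and the normal approximation with continuity correction (on
midranks) otherwise. Gene-set enrichment is a self-contained upper-tail
hypergeometric test per set with Benjamini–Hochberg adjustment across sets
(significant at FDR ≤ 0.05); the universe is the set of measured genes —
the screening context — not all annotated genes. No external enrichment
service is called.

## Synthetic data generator

The generator provides the statistical structure the pipeline assumes, so
every stage is testable without external downloads:

- per-gene log2 expression i.i.d. normal, mean ~ U[4, 12], sd ~ U[0.5, 2];
  an optional block-correlation mode shares a latent factor within gene
  blocks to stress collinearity handling;
- target `y = β₀ + Σ βⱼ·zⱼ + lineage_offset + ε` on the −log10(M) scale,
  with zⱼ the causal gene standardized by its *generative* mean/sd (train
  and blind partitions therefore follow exactly one law),
  ε ~ N(0, noise_sd²), and IC50 = 10^(−y);
- defaults: 52 solid training lines plus 6 blood-lineage lines with an
  additive −1.5 offset (toward resistance), 37 blind solid lines, 2000
  genes, five causal genes — one dominant at β = 1.5 and four at β = 0.4 —
  noise_sd = 0.3, β₀ = 6.5 so typical IC50s fall in the nM–µM band, eight
  tumor types;
- companion fixtures: a GMT collection whose first set contains every
  causal gene (the known-target-pathway analog) and a sparse Erdős–Rényi
  SIF network in which causal genes are wired as mutual neighbors.

What the generator does **not** emulate: real covariance structure between
genes, batch or platform effects, heteroscedastic microarray noise,
non-additive genetics, or dose-response curve-fitting error. Passing tests
therefore demonstrate that the machinery is correct and recovers planted
structure under its stated law — not that a particular biological signature
is right.

### A detectability note that shapes the tests

With the default effect sizes, the target's sd is
√(1.5² + 4·0.4² + 0.3²) ≈ 1.73, so each weak causal gene has population
correlation 0.4/1.73 ≈ 0.23 with y — at n = 52 that is typically
non-significant and carries Boruta hit rates indistinguishable from noise.
The funnel reliably recovers the dominant driver (and weights it like the
real screen weights its activating enzyme), but weak β = 0.4 effects sit
below the information limit of a 52-sample screen, and the variance they
carry bounds the blind-set accuracy of any derived model. The blind-transfer
analysis therefore reports two models side by side: the derived signature
and the same ensemble fit on the planted causal genes (the transfer
ceiling, the analog of carrying the full causal biology to a new cohort).
Script `analysis/03_blind_evaluation.py` and `scripts/acceptance.py`
compute both.

## Determinism and seeds

One master seed drives everything; per-stage seeds derive from it by fixed
offsets so no two stages share a stream. Relief uses all samples (no
sampling); LightGBM runs single-threaded with `deterministic=True`; the
random forest, CV fold assignment, the train/holdout split and all
generators take derived seeds. Two runs with the same config and seed
produce byte-identical artifact files; this is asserted by a test and
recomputed by the acceptance script.

## Problem sizes used by the test suite and acceptance script

Unit tests run on panels of 20–60 samples and 20–300 genes. The
whole-pipeline studies use the generator defaults (58 training lines
including blood, 37 blind, 2000 genes) over ten seeds; Boruta error control
uses 100 samples × 100 features with 20 all-noise seeds and 10
planted-signal seeds; determinism uses a 500-gene panel. These sizes keep
each study in the minutes range on a single core while leaving the
generative law itself untouched.

## Known limitations

- Sample matching is exact-string; no alias reconciliation across panel
  nomenclatures.
- The pathway/network filters are containers for user-supplied GMT/SIF
  content; no curated database ships with the package.
- The elimination criterion rides on an 11-line holdout and is accordingly
  noisy; the trace is written out precisely so that choice can be audited.
- Boruta's tentative verdicts are excluded from signatures; on weak data
  this can shrink signatures to very few genes (the top-up rule guarantees
  only that elimination can run).
- Exact Wilcoxon p-values are limited to groups ≤ 10 without ties.
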