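# Methods

## Scope

`microcross` implements the evaluation machinery used to ask whether gut
microbiome classifiers trained on one case-control cohort generalize to
independent cohorts of the same disease: preprocessing of taxon
relative-abundance tables, removal of within-cohort confounders and
cross-cohort batch effects, nested cross-validated classifiers, four
evaluation designs (intra-cohort, cross-cohort, leave-one-dataset-out,
cohort cumulation and sample cumulation), signed LDA effect-size marker
calling, and the Marker Similarity Index (MSI) that quantifies cross-cohort
marker consistency.  A synthetic multi-cohort generator with known ground
truth drives every stage, so each claim the package makes is testable
without downloading data.

## Synthetic multi-cohort generator

The generator emulates the structure of curated multi-cohort disease
collections, not any particular sequencing protocol.  All shifts act in
log2 space:

* **Baselines.** Each taxon draws a global baseline log2 abundance from
  N(0, `base_sd`=2), giving heavy-tailed, rank-realistic lognormal profiles
  after exponentiation.
* **Batch effects.** Each cohort adds a per-taxon shift from
  N(0, `batch_sd`=1) — systematic, label-independent between-cohort
  variation.  With these defaults a cohort-identity classifier is nearly
  perfect while a label classifier stays at chance when no disease effect is
  injected (tested).
* **Samples.** Per-sample noise N(0, `sample_sd`=1.5) per taxon; entries
  drop to exact zero with probability `zero_prob`=0.3 (detection limit);
  each sample is then closed to sum 1.
* **Markers.** `n_markers`=25 taxa, drawn from the upper 60% of baseline
  abundance (real curated markers are detectable taxa; this also keeps the
  injected signal comparable across seeds), are multiplied by
  `2**(sign*effect_size)` in cases before dropout and closure
  (`effect_size`=4, i.e. a 16-fold change).  A fraction `consistency_rho`
  of markers is shared by all cohorts with a fixed direction; the rest are
  drawn independently per cohort from the non-shared pool with per-cohort
  directions.  `consistency_rho` is therefore the single knob connecting the
  generator to external-validation AUC and to the MSI.
* **Cohort sizes.** Five cohorts of 48 cases / 47 controls by default, the
  median group sizes of curated multi-cohort disease collections.
* **Confounders** (off by default). A binary or quantitative covariate that
  correlates with the label at a configurable odds ratio / mean shift and
  shifts a marker-free taxon subset.

Defaults were fixed once so that the full default pipeline (QC, batch
correction, nested-CV lasso) lands at the intra-cohort AUC operating point
reported for well-powered real cohort collections (median ~0.8 across
seeds).  What the generator does **not** emulate: phylogenetic correlation
between taxa, abundance-dependent dropout, read-count noise, protocol
differences beyond additive log-scale shifts, and multi-disease structure.
Passing tests therefore demonstrate internal consistency of the machinery
and directional behavior under known truth — not performance on any real
cohort.

## Preprocessing

* **QC.** Samples with ≤2 detected taxa are removed; taxa whose relative
  abundance is below 0.001 in every sample are removed.  The two rules are
  iterated to a fixed point (making the filter idempotent) and survivors
  are not renormalized.
* **Confounder detection.** Within a cohort, categorical covariates are
  tested case-vs-control with two-sided Fisher's exact tests (chi-square
  for >2 levels), quantitative covariates with two-sided Wilcoxon rank-sum
  tests; covariates with p < 0.05 are flagged.  Tests are assigned by
  variable type — the statistically coherent mapping.
* **Confounder removal.** Per taxon, OLS of log10(x + 1e-6) on intercept +
  label + flagged covariates; the mean-centered covariate contribution is
  subtracted and the result back-transformed and floored at 0.  The label
  stays in the design so the case-control contrast is never absorbed.
* **Batch correction.** A zero-preserving empirical-Bayes location/scale
  correction of per-taxon log10 abundances across cohorts (ComBat-style):
  non-zero entries are fitted with cohort indicators + label, standardized
  by the residual sd, and the per-cohort location/scale of the standardized
  data is shrunk toward grand parameters (normal / inverse-gamma priors,
  method-of-moments hyperparameters, joint posterior-mode iteration) before
  removal.  Zeros stay zero; samples are renormalized to sum 1.  Including
  the cohort indicators in the standardization fit is essential: without
  them batch shifts inflate the pooled residual scale and the rescaling
  distorts label effects across cohorts.
* Marker calling operates on confounder-adjusted tables; modeling operates
  on confounder- and batch-adjusted tables.

## Normalization, balancing, models

Features are normalized with the log-std convention: log10(x + 1e-6), then
per-feature z-scores whose sd is floored at the 0.1 quantile of all feature
sds.  Parameters are frozen on training data; external cohorts are mapped
onto the training feature list with raw zeros for absent taxa before the
frozen transform (the external-validation zero-fill contract).

Imbalanced training sets (majority/minority ≥ 3) are rebalanced with SMOTE:
each minority sample contributes max(3, round(majority/(2·minority)))
synthetic points, each a uniform convex combination of the sample and one
of its k=5 nearest minority neighbors.  By default SMOTE runs inside
training folds only (leak-free); `smote_mode="cohort"` reproduces the
whole-cohort application some published pipelines use, which leaks
information across folds and is provided only for comparability.
Normalization precedes SMOTE, so interpolation happens in standardized
space.

Classifiers are L1-penalized logistic regression by default (elastic net,
ridge and random forests behind the same interface), trained with repeated
stratified nested CV: 5 outer folds × 3 repeats within one cohort, 10 × 3
for pooled designs; hyperparameters are chosen per outer split by an inner
5-fold grid search (20 log-spaced C values in [1e-3, 1e3]; ties resolve
toward stronger regularization) run strictly on the outer-training portion,
where normalization, optional top-N single-feature-AUC selection and SMOTE
are also fitted.  External prediction averages the scores of all stored
fold models.  Internal AUC is the mean over repeats of the out-of-fold AUC.

## Metrics

AUC is the Mann-Whitney rank estimator with half credit for ties (verified
against exhaustive pair counting).  AUC-PR uses step interpolation, which
avoids the optimistic bias of trapezoidal interpolation on precision-recall
curves.  MCC uses a 0.5 score threshold (configurable) and is defined as 0
when a confusion-matrix marginal is 0.

## Marker calling and MSI

Marker calling follows the two-stage LEfSe recipe for two classes: profiles
are rescaled to sum 1e6 per sample; taxa pass a two-sided rank screen
(p < 0.05); surviving taxa receive a bootstrapped linear-discriminant
effect size — over 30 rounds of 2/3-per-class subsampling, a ridge-
stabilized (epsilon 1e-6) two-class LDA is fitted and each taxon scores the
mean of (a) its absolute class-mean difference and (b) |unit discriminant
weight × projected class-mean difference|; the final score is
log10(1 + bootstrap mean).  This reduces to log10(1 + d) for a single taxon
with class-mean difference d (the closed form used in tests) and reproduces
the conventional 2–6 score range on the 1e6 scale.  Taxa scoring ≥ 2 are
markers, signed + for case-enriched and − for control-enriched.  Because
relative abundances are compositional, strong markers also drag other taxa
into genuine (secondary) differential abundance; the caller reports what the
data show, exactly as the original tool does.

MSI compares two signed marker score vectors asymmetrically.  With the
reference A carrying p markers, the target B is aligned to A's taxa (extras
dropped, absences zero-filled) and MSI(A→B) = p / ‖m_A − m_B‖₂.  One or no
reference marker gives MSI 0; identical aligned vectors are flagged
degenerate and floored at p/1e-8 rather than returned infinite, so
downstream medians stay finite.  MSI rises monotonically with the
generator's `consistency_rho` and correlates positively with external
validation AUC across consistency levels (tested).

## Designs and downstream statistics

* **intra/cross:** one model per cohort; out-of-fold internal AUC plus
  external validation on every other cohort.
* **LODO** (≥3 cohorts): train on all-but-one pooled, test the left-out
  cohort; pooling is audited against sample leakage.
* **CCM** (≥5 cohorts): training pools of 2..K−1 cohorts; all subsets when
  ≤ 20 per size, else 20 seeded draws.
* **SCM** (≥5 cohorts): balanced 1:1 case:control draws of growing size from
  the LODO pool (grid 16..40 step 6, then 60..max step 20, capped at the
  balanced pool), 10 draws per point by default, tested on the left-out
  cohort.
* **Sample-size extrapolation:** OLS of median external AUC on training
  size, inverted at the target AUC and rounded up to the grid step; the 95%
  CI inverts the regression's prediction interval (the CI always contains
  the point estimate; a non-positive slope reports "not attainable" rather
  than a number).
* **MSI↔AUC linkage:** Spearman correlation over (train, test) pairs of the
  MSI (reference = training cohort) against external AUC.

A master seed fans out to per-stage seeds through a splitmix64 derivation,
so a full run is byte-reproducible and stages can be reproduced in
isolation.

## Problem sizes used by the test and acceptance suites

End-to-end checks run on scaled-down versions of the default conditions,
chosen to exercise every design while staying desk-sized: null calibration
uses 20 seeds of 3 cohorts × (40+40) × 120 taxa with effect 0; the
consistency contrast uses 3 seeds × 3 cohorts at the default conditions for
rho ∈ {0, 1}; the LODO comparison 6–10 seeds at rho 0.5; the SCM trend one
left-out cohort of a 5-cohort rho=1 simulation over the grid
16..40(+6), 60..100(+20) with 3 draws per point; the MSI linkage one
simulation per rho ∈ {0, 0.25, 0.5, 0.75, 1}.  These runs use single-repeat
nested CV; the library defaults remain 3 repeats.

## Known limitations

* The generator's independence assumptions (taxa, samples, dropout) are
  optimistic; real effect transfer across cohorts is harder than the rho=1
  condition suggests.
* The batch model is additive in log space; multiplicative library-size or
  protocol interactions are not represented.
* Linear-model bundles serialize to TSV/JSON; random-forest models predict
  in-session but do not serialize.
* Fisher's exact test falls back to chi-square for categorical covariates
  with more than two levels.
* The LDA effect size is one member of the family of bootstrap LDA scores;
  absolute score values depend on this choice, while rankings and the MSI
  comparisons are stable across reasonable variants (the cutoff sweep
  behavior is tested).
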