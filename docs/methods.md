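# Methods

## The analysis this package implements

`ewasrf` implements a two-stage epigenome-wide association analysis for a
binary allergic phenotype (atopy, with high total serum IgE as a secondary
biomarker) measured on Illumina 450K methylation arrays of whole blood.

**Stage 1 — recursive Random-Forest feature selection.** Starting from all
probes surviving quality control, a Random Forest is grown on the discovery
subsample; probes are ranked by mean-decrease-Gini (MDG) importance, the
bottom half is eliminated, and the forest is regrown on the survivors,
iterating while tracking the overall out-of-bag (OOB) error and the
per-class OOB misclassification rates. Because the atopic class is the
minority class and the one the analysis most cares about classifying
correctly, selection is governed by the *focal-class* (atopic)
misclassification trajectory.

**Stage 2 — covariate-adjusted logistic association.** The selected CpGs
are tested one at a time by logistic regression of the outcome on the CpG's
M-values, adjusted for estimated proportions of six leukocyte types (CD8+ T,
CD4+ T, NK, B cells, monocytes, granulocytes) and sex, with Bonferroni
control at family alpha 0.05 over the selected set. A replication filter
then requires, in an independent cohort's per-CpG results, the same
direction of association (odds ratio on the same side of 1) and p < 0.05.

## Value scales

Betas are intensity proportions `beta = M/(c + M + U)` (offset `c` defaults
to 100, the array-software convention) and feed the forests, which are
scale-free. Parametric models use M-values `log2(beta/(1-beta))`, which are
approximately homoscedastic; the transform refuses beta in {0, 1} unless an
explicit epsilon clip is requested. The round trip `m_to_beta(beta_to_m(.))`
is an identity to better than 1e-12 on (0.001, 0.999).

## Quality control

Filters run in a fixed order and only ever remove probes:

1. **Detection**: a probe is removed when its detection p exceeds 0.01 in
   *strictly more than* 10 % of samples (a probe failing in exactly 10 % is
   retained).
2. **Sex chromosomes**: probes with manifest chromosome X or Y.
3. **SNP-flagged probes**: manifest boolean flag for a possible variant in
   the probe body or at single-base extension.

A `FilterReport` reconciles counts exactly (entry − removals = remaining)
and keeps the per-stage probe lists. Batch effects are handled by a
location-scale adjuster: per probe, each batch's values are standardized
and mapped onto the pooled mean and SD. This deliberately simple aligner is
the default behind an extension point where an empirical-Bayes adjuster
could be slotted; probes with zero within-batch variance pass through, and
singleton batches are rejected unless location-only alignment is requested.

Outliers in stage-2 M-values are recoded to missing by a Tukey fence,
`[Q1 − k·IQR, Q3 + k·IQR]` with `k = 3` by default, computed per probe
within outcome strata. A fence (rather than an SD rule) is robust and
reproducible; `k = 3` flags only gross artifacts. Missing values are then
case-wise deleted per regression fit; forest inputs are mean-imputed within
outcome class (forests cannot hold NaN).

## Cell-type deconvolution

Bulk blood methylation mixes cell-type methylomes roughly linearly on the
beta scale, so per-sample proportions are estimated by constrained least
squares against a reference matrix (probes × cell types): minimize
`||R w − y||²` subject to `w ≥ 0` and `Σw ≤ 1` (default) or `Σw = 1`
(normalized mode). The default inequality form reports the unexplained
remainder through the residual instead of forcing it into the weights. The
problem is solved by NNLS on an augmented system with a slack variable and
a heavily weighted sum row, which is deterministic and accurate to machine
precision on these small (6-column) problems; tests cross-check small cases
against a 0.01-step grid search over the simplex. Projection uses all
probes shared between sample and reference; a rank/conditioning guard
rejects degenerate references.

## The forest primitive

Each tree is CART (scikit-learn's implementation) grown to purity on a
*per-class bootstrap*: `sampsize = (50, 50)` draws, with replacement, 50
members of each outcome class per tree, neutralizing the class imbalance
(roughly 31–41 % positive) that would otherwise let the majority class
dominate; `sampsize = None` gives the classic pooled bootstrap. `mtry`
accepts an integer or the rule tags `sqrt_p`, `2sqrt_p`, `0.05p`, `0.1p`,
`0.5p` (floor, clamped to [1, p]; rule tags re-resolve as the variable set
shrinks during elimination).

OOB votes are accumulated per sample over the trees whose bootstrap
excluded it; predictions are majority votes with ties broken toward the
lower class label; samples never OOB (possible at small ntree) are excluded
from error denominators and counted in `n_oob_covered`. The reported
overall OOB error is, by construction, the class-size-weighted mean of the
per-class errors over covered samples — the tests recompute it from the
stored vote matrix and require exact equality.

MDG importance is the weighted Gini impurity decrease summed over each
tree's splits on the variable, normalized by the tree's root sample weight
and averaged over the forest. It is nonnegative and invariant to the number
of trees in expectation.

## Recursive elimination and the stopping rule

Variable counts follow floor-halving: from 254,460 probes the schedule is
254,460, 127,230, 63,615, 31,807, …, 62 (iteration 13), 31, 15. When p is
odd the *larger* "half" is removed (keep floor(p/2)). Ranking ties are
broken lexicographically by probe ID so traces are reproducible.

Two stopping policies are provided:

* `first_increase` — stop at the first iteration whose focal-class error
  strictly rises; select the iteration before it.
* `global_min` (default) — run the whole schedule and select the iteration
  minimizing focal-class error, ties broken by fewer variables, then lower
  overall OOB error.

The default is `global_min` because a literal first-increase rule is fragile
against transient upticks in the error trajectory (the published trajectory
this mirrors passes over exactly such an uptick and selects the global
minimum of the focal-class error); `first_increase` reproduces the stated
rule for comparison. Per-iteration forests are reseeded as
`master_seed + iteration`, so a trace is a pure function of data and master
seed.

## Association testing

Fits are maximum-likelihood logistic regressions (statsmodels, Newton
iterations, score tolerance 1e−8, at most 100 iterations) with two-sided
Wald p-values. Separation — non-finite or diverging coefficients (|b| > 50)
or a solver failure — raises a flagged error; in the batch driver the probe
is skipped and logged rather than reported with a meaningless estimate. A
condition-number guard (10^8 on the standardized design) rejects collinear
covariates naming the columns; the driver retries once after dropping a
constant column or, failing that, the largest-mean cell-type proportion.
All six cell-type proportions plus sex enter as covariates; with the
`Σw ≤ 1` deconvolution mode they are not exactly collinear.

The confounding diagnostic reports
`%diff = 100·(adjusted − crude)/crude` for each CpG. (The sign convention
follows the published tables, where crude −1.18 → adjusted −1.43 is printed
as +21.45 %.) The significance filter is strict (`p < alpha`), and the
Bonferroni per-test alpha is `0.05/m` over the m selected CpGs
(0.05/62 = 8.06E−4 in the motivating analysis).

The 2×2 prevalence comparison uses Pearson's chi-square with the Yates
continuity correction by default: recomputing the published female-vs-male
high-IgE comparison (24/77 vs 18/25) gives p = 0.047 only with the
correction, and the atopy comparison (76/166 vs 49/71) gives the printed
0.0972 likewise.

## Replication

A discovery CpG replicates when the external cohort reports an odds ratio
on the same side of 1 and p strictly below 0.05. An OR exactly 1 has no
direction and never counts as concordant (logged). Probes absent from the
external set are excluded from the tested denominator. On the packaged
published summary columns this yields 19 available of 22 discovery sites
and 13 replicated.

## The synthetic generator

`generate_dataset` emulates the study's data-generating structure: a
discovery subsample (default 245, all one sex, batch 1) plus a later
addition (default 122, the other sex, batch 2); outcome prevalence 0.35
(the cohort range is roughly 31–41 %); six cell types with blood-like mean
proportions (granulocytes ≈ 0.53) drawn per sample from a Dirichlet whose
granulocyte mean shifts by `confound_strength` in cases; bimodal baseline
methylomes with cell-type-discriminating offsets; planted outcome effects
of `effect_size` (default 2.0) on the M scale at `n_informative` autosomal
probes with random signs; X-inactivation-like sex probes; trimodal
SNP-affected probes; an additive M-scale batch offset; and detection
failures at a configurable rate. Bulk profiles are mixed on the beta scale
and perturbed on the M scale, so betas stay strictly inside (0, 1).

The residual M-scale noise SD defaults to 1.5, the within-class spread of
typical variable 450K probes. With the default planted shift of 2.0 this
gives a standardized effect near 1.3 — a strong but realistic signal;
materially smaller noise would make planted probes perfectly separate the
classes, a regime in which logistic coefficients are undefined.

What the generator does **not** emulate: genomic autocorrelation between
neighbouring CpGs, Infinium I/II chemistry differences, raw IDAT-level
artifacts, and realistic linkage between SNP genotypes and outcome. Passing
tests therefore demonstrate the pipeline's statistical machinery under the
assumed mixture-plus-shift model, not performance on real cohort data.

## Problem sizes used by the test and acceptance experiments

The published analysis ran on 254,460 probes and 245/367 samples; the
package's experiments run the identical algorithms at reduced sizes chosen
to exercise every code path with comfortable margins: recursive-selection
recovery uses 500 probes (5 planted, effect 2.0), n = 200, ntree = 500,
ten seeds; the null family-wise-error experiment uses 100 replicates of 40
null probes with 60 + 60 samples; deconvolution recovery uses 200 mixtures
over 400 probes at beta-noise SD 0.02.

The null experiment is run with *disjoint* stage-1/stage-2 samples
(`stage2_pool=False`). Under the default pooled design — which mirrors the
published analysis — stage-2 tests reuse the samples that drove stage-1
selection, and the resulting optimism inflates the family-wise error above
its nominal level; this non-independence is a known limitation of the
two-stage design, reproduced as-is by the default. Bonferroni control is a
valid claim for data independent of selection, which the disjoint
configuration provides.

## Known limitations

* The batch adjuster is location-scale only; no empirical-Bayes shrinkage.
* MDG importance is biased toward variables with many split points; the
  pipeline inherits this property of Gini-based forests.
* The deconvolution reference is an input; estimating it from sorted-cell
  data is out of scope, as is separating eosinophils from other
  granulocytes.
* Under the pooled two-stage design, stage-2 p-values at selected probes
  are optimistic (see above).
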