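# Methods

## Overview

The package turns a gene-by-sample raw count matrix and a clinical table
into a per-tumor malignancy score (SAHR) in five stages: count
normalization, tumor-vs-normal differential expression, median-split
survival screening with four-way categorization, panel training /
scoring / transfer, and stratified survival evaluation. A synthetic
cohort generator with planted ground truth backs the validation suite.
This note records the model in each stage, the tunable parameters and
their defaults, the numerical choices, and what the synthetic checks do
and do not establish about real data.

## Normalization

Size factors follow the median-of-ratios construction: the reference is
the per-gene geometric mean over all samples, restricted to genes with
nonzero counts in every sample; a sample's factor is the median ratio of
its counts to the reference, and normalized expression is counts divided
by the factor. No rescaling is applied afterwards, so doubling one
sample's library yields factors (1/√2, √2) in a two-sample matrix — the
normalized values, which are all downstream stages consume, are
invariant up to a single global constant. When no gene is expressed in
all samples the fit fails loudly; an explicit
`allow_pseudo_reference=True` opts in to a geometric mean over nonzero
counts only. The transformer keeps its fitted reference, so cohorts
normalized later are on the training scale.

## Differential expression

A gene is differentially expressed when its Benjamini-Hochberg adjusted
p-value is below 0.01 and |log2 fold change| ≥ 1 (at least 2-fold).
The fold change is log2((mean tumor + c)/(mean normal + c)) on
normalized values with pseudocount c = 1; the p-value comes from Welch's
t-test on log2(normalized + 1). The BH step-up is implemented directly
(sorted p·m/rank with a reverse cumulative minimum) and is checked
against the brute-force definition and against statsmodels. Ribosomal
RNA genes are removed before testing from a caller-supplied list; the
package deliberately does not guess rRNA identity from annotations.

Design note: the two-group test is Welch's t on log counts rather than a
negative-binomial Wald regression. Downstream stages consume only the
call (direction + significance at stringent thresholds), for which the
t-test on normalized log counts is adequate and dependency-free; an
NB-GLM backend would slot in behind the same `test_differential`
surface. Dispersion shrinkage, independent filtering and LFC shrinkage
are out of scope.

## Survival statistics

All survival statistics are implemented in-house and validated against
brute-force oracles and lifelines:

- **Kaplan-Meier**: product-limit estimator; censorings tied with an
  event time remain at risk for that event.
- **Cox regression, binary covariate**: Efron tie correction. For a
  binary covariate the partial likelihood at each distinct event time
  depends only on the at-risk and event counts per group, so the score
  and information are closed forms; Newton-Raphson starts at β = 0 with
  step-halving on likelihood decrease, converges at |Δβ| < 1e-8 (max 50
  iterations). Efron was chosen over Breslow because discretized
  synthetic times produce heavy ties. p-values are Wald; the 95% CI is
  Wald on the log scale; the log-rank p is attached as an auxiliary.
- **Monotone-likelihood guard**: |β| > log 50 marks a non-identified
  fit; the coefficient is capped, the result flagged and a warning
  raised — flagged hazard ratios are excluded from panel training and
  never reported without their flag.
- **Log-rank**: standard two-group chi-squared with 1 df, hypergeometric
  variance per event time.
- **Kruskal-Wallis**: tie-corrected H with a chi-squared (k−1) p-value;
  all-tied input returns H = 0, p = 1.

## Prognosis screening and categorization

Each DEG is dichotomized at its median normalized expression over the
screening tumors; values strictly above the cutoff form the
higher-expression group (ties go lower). If more than 30% of the
screening tumors have expression exactly 0, the cutoff is 0 instead:
unexpressed tumors are the lower group. The zero fraction is evaluated
on the screening tumors only (training half by default), not the whole
cohort, to avoid test-set leakage; `use_split="all"` restores
whole-cohort screening for descriptive catalogs. Genes whose split
leaves one group empty are marked unsplittable and excluded.

The Cox covariate is membership of the *lower*-expression group, so
exp(β) is directly HR(lower vs higher). With the DE direction this maps
onto four categories (see README table); genes with Wald p ≥ 0.05 stay
uncategorized. The stored hazard ratio is re-oriented worse-vs-better,
i.e. max(HR, 1/HR) ≥ 1.

The train/test split is random 50/50, stratified by the event indicator
and fully seeded.

## SAHR panel, scoring, transfer

Panel training takes, per category, the smallest-p genes up to the
limits (20 oncogene-like, 20 suppressor-like, 10 up-regulated-saver,
10 down-regulated-saver), after discarding flagged fits and hazard
ratios above 20; discarded genes free their slots. p ties break by
larger hazard ratio, then lexicographic gene id, so models are
deterministic. Categories with fewer survivors contribute what they
have; a sub-60-gene panel is valid and logged.

Scoring assigns δ = +1/−1 per panel gene from the cutoff comparison
(value exactly at the cutoff counts as lower) and sums δ·HR. Scores of
exactly 0 — a measure-zero event — go to the negative (lower-risk)
group, reading "positive" strictly as score > 0. Transfer onto a new
cohort intersects the panel with the target's genes, re-anchors each
cutoff at the target cohort's median and keeps the training hazard
ratios; callers must pass tumors only, since normals would shift the
medians. Because medians and threshold comparisons are rank statistics,
any strictly monotone per-gene transformation of the target data leaves
every δ pattern and score unchanged — this is what makes cross-platform
transfer defensible, and it is enforced by a property test.

## Evaluation

`evaluate_stratification` compares SAHR-positive vs SAHR-negative
patients by the binary Cox fit with per-group KM curves; degenerate
splits are refused, never silently scored. `stage_stratified_eval`
repeats the comparison inside early (I–II) and late (III–IV) stages —
the boundary is fixed at II|III — excluding and counting unknown
stages; a degenerate stratum is reported as not evaluable.
`sahr_vs_stage` tests the score-vs-stage trend by Kruskal-Wallis.
`run_pipeline` chains every stage deterministically from one seed,
writes all artifacts as TSV, and keeps a sample ledger so every tumor is
accounted for (kept + excluded at each stage equals the input count).

## Synthetic cohorts

`simulate_cohort` emulates exactly the structure the analysis assumes:

- **Counts**: negative binomial with variance μ + φμ² (default
  dispersion φ = 0.2, a typical bulk RNA-seq value), gene baseline means
  log-uniform on ln-mean ∈ [1.5, 8] (≈ 4–3000 counts), per-sample
  log-normal size factors (sd 0.3).
- **DE contrast**: planted genes get ±de_log2fc (default 2, i.e.
  4-fold) in tumors; oncogene-like / up-regulated-saver genes are up,
  the other two categories down.
- **Survival**: tumor times are exponential with hazard
  h₀·exp(Σ_planted sign·log(HR)·z), where z indicates normalized
  expression above the tumor median and the sign follows the category
  (risk = high expression for oncogene-like and down-regulated-saver,
  low expression for the other two). The exponential baseline makes
  proportional hazards exact. Censoring is independent uniform with the
  upper bound solved by Brent search so the expected censoring fraction
  hits the target (default 30%); planted_hr = 1 gives an exact survival
  null. Normals carry no follow-up.
- **Defaults are the reference study conditions**: 500 genes, 400
  tumors, 50 normals, 10 planted genes per category, per-gene HR 2.5.
- **Zero inflation**: an optional fraction of planted genes receives
  per-tumor dropout to exercise the >30%-zeros cutoff rule.
- **Structure**: stages are drawn independently of expression
  (0.35/0.30/0.25/0.10 for I–IV), so stage-stratified checks probe pure
  score signal; the train/test split is event-stratified.

Gene-level truth (planted identities, baselines, fold changes) derives
from `config.seed`; sample-level noise from a separate `cohort_seed`.
Two cohort seeds under one config therefore give independent cohorts
from the same generative truth — the design used by the held-out
discrimination check.

### What the generator does not emulate

No batch effects, GC/length bias, gene-gene correlation, per-gene
dispersion trends, non-proportional hazards or informative censoring.
Passing tests therefore establish internal statistical correctness —
calibration, recovery, invariances — not robustness to the systematic
artifacts of real cohorts.

### Marginal attenuation of planted effects

With 40 planted genes the per-sample log-hazard spread (variance ≈ 8.4)
acts as unobserved frailty on every univariable screen: the marginal
median-split hazard ratio of a single planted gene saturates near 1.4
even though its conditional hazard ratio is 2.5, and the power of the
α = 0.05 screen at n = 400 is ≈ 0.70 per gene. This is a property of
the many-genes generative model, not an estimator defect: with a single
planted gene the marginal and conditional effects coincide and the Cox
estimator recovers HR 2.0 with mean ≈ 1.91–1.95 over 100 cohorts
(the remaining ~3% shrinkage comes from size-factor estimation
occasionally flipping samples near the median). The held-out SAHR
discrimination check is unaffected because the panel aggregates all
planted genes.

## Problem sizes used in validation

Oracle equivalence uses 200 random Cox instances (n ≤ 8, heavy ties),
1,000 random BH vectors and 200 random KM samples; error control uses
50 survival-null cohorts of 200 tumors; recovery uses 20 cohorts at the
reference conditions and 100 single-gene cohorts; discrimination uses
50 train/validate cohort pairs. These sizes give binomial standard
errors of ~0.5–1.5 percentage points on the reported rates.

## Known limitations

- The DE stand-in is a t-test, not an NB model; very low counts with
  few replicates will be miscalibrated compared to a dedicated DE tool.
- Univariable screening ignores gene-gene correlation; panels can carry
  redundant genes.
- Survival times are unit-agnostic; callers must keep one unit per
  cohort.
- The score is a proof-of-concept linear aggregate with ±1
  coefficients; no regularized or continuous-coefficient variant is
  provided.
- Multivariable adjustment of the score for stage (beyond stratified
  reporting) is out of scope.
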