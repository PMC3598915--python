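# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `survtransfer`.

## Survival estimators

All estimators operate on right-censored outcomes (T_j, δ_j), δ_j = 1 for
an observed event.

**Cox proportional hazards.** `cox_fit` maximises the partial likelihood
by Newton–Raphson with the Efron correction for tied event times (Breslow
available via `ties="breslow"`). Iteration starts at β = 0 with tolerance
1e-8 on the score norm, at most 50 iterations, and step-halving whenever a
full Newton step would decrease the likelihood. Columns are standardised
internally (the estimate is transformed back), which makes conditioning
and the separation diagnostic scale-free: a fit whose score vanishes while
a per-standard-deviation standard error exceeds 100 carries no curvature
information and is flagged `converged=False` (monotone likelihood /
separation) rather than returned as a spurious maximum. Standard errors
come from the inverse observed information. When no two events share a
time the Efron and Breslow accumulations coincide and a fully vectorised
path (reverse cumulative sums over the risk sets) is used; tied data go
through the generic per-event-group loop. Both paths agree exactly on
tie-free data.

**Kaplan–Meier and log-rank.** The product-limit estimator and the
k-sample log-rank test use the standard hypergeometric moments; the
statistic is (O−E)ᵀV⁻¹(O−E) over the first k−1 groups with a χ²(k−1)
reference. Two groups is the routine case; the k-sample form also scores
the multi-leaf grouping induced by a fitted tree.

**Survival tree.** Greedy binary partitioning: at each node the split
maximising the two-sample log-rank statistic is chosen among splits
leaving ≥ `min_leaf` (default 20) patients per side, subject to a
significance gate p < 0.05 that keeps noise covariates from growing the
tree (the admission threshold is configurable; depth ≤ 3 by default).
Numeric splits test midpoints of adjacent unique values (capped at 50
quantile candidates); categorical splits enumerate binary level partitions
up to 8 levels, beyond that prefix splits of levels ordered by incidence
rate. Leaves store the incidence rate, events per unit person-time —
0 for an all-censored leaf. Ties in the split statistic resolve to the
first candidate in column/threshold order, so fitting is deterministic.
Routing a sample with a categorical level unseen on either side of a
training split raises a routing error naming the sample, rather than
guessing a branch.

## The eight risk models

Univariate Cox screening keeps genes with Wald p ≤ `selection_threshold`,
ordered by ascending p with exact ties broken by gene id. The library
default is 0.001; analyses on small cohorts typically need a looser
cutoff (the worked examples use 0.01–0.05), and the threshold is a free
parameter because no canonical value exists. Model C centers the
signature genes by their training means (no variance scaling — log-scale
expression values are already comparable) and takes loadings from the SVD
of the centered training matrix; the first k = 5 PC scores enter a Cox
fit, and prediction projects new data onto the frozen training means and
loadings. Model D uses the k = 10 smallest-p genes directly (all selected
genes, with a warning, if fewer pass). Model B converts the clinical tree
to a single covariate — each patient's leaf incidence rate — and fits a
univariate Cox model on it; prediction routes test patients through the
frozen training tree. "Additive" combinations E–H are one joint Cox refit
on the union of the parents' design columns, because each combined model
must produce a single linear predictor and a single hazard ratio; they
are not sums of two separately fitted score vectors.

Categorical clinical covariates expand to treatment-coded indicators
against the most frequent training level; stage is ordinal numeric by
default (categorical via configuration). The indicator level set is
frozen at training time so the design width is identical on any test
center. Stage enters the generator and the models on the same ordinal
scale, so coefficient recovery is directly comparable.

`apply_signature` transplants a fitted model's gene signature to another
dataset and re-estimates everything else there (PC means, loadings, all
coefficients). For the clinical-only kinds A and B there is nothing to
transplant and the operation is exactly a local fit — which forces
ρ₃ = 1 and ρ₁ = ρ₂ in the resampling procedure, a structural identity the
tests assert.

## Performance measures

**Somers' D_xy.** Usable pairs are those whose time ordering is
determinable under censoring (the shorter time has δ = 1; tied times are
unusable); a pair is concordant when the shorter-lived patient has the
lower score, tied scores count ½. D_xy = 2c′ − 1 with c′ the concordant
fraction. Because D_xy is the rank correlation between *score* and
*time*, a well-performing model has negative D_xy. The companion signed
concordance index carries the better-oriented magnitude max(c′, 1−c′)
with the sign of D_xy, and `dxy_from_cindex` inverts it as
D = sign(c)·(2|c|−1), so the pair (c = −0.6033, D_xy = −0.2066) is
self-consistent.

**R².** The explained-variation statistic 1 − exp(−LR/n) from the
univariate Cox fit of the scores (the quantity standard Cox software
prints). Other R² variants exist for censored data; this one was chosen
as the de-facto default and is stated here because the choice is not
canonical.

**ROC(t).** Cases are patients with an observed event by t, controls are
patients followed beyond t; patients censored before t are unclassifiable
in the 2×2 count and are excluded, with `n_excluded` reported. For each
cutoff c, TPR and FPR are simple counting proportions, so the curve is
monotone with no negative probability mass by construction, closed at
(0,0) and (1,1); AUC by trapezoid. Evaluation times are configurable;
presets: "lung" = month 36, "colon" = months 23/42/68 (quartiles of
follow-up).

**Two-group comparison.** Threshold = median of the *training* scores;
test patients strictly above it are high-risk (ties at the median go
low-risk, a deterministic convention). A split with an empty group, or a
group containing no events, returns NA instead of raising, so batch
tables render NA rows for degenerate models rather than aborting.

## Reproducibility statistics

`crosscenter_table` estimates each center's model on its **entire**
dataset and evaluates every correlation once (for m+1 centers, each
target has m transferability rows and C(m,2) consistency rows; four
centers give 3 + 3 rows per target). `resample_signature_transfer` uses
**partial** data: per repetition, center B is split without replacement
into `n_train` (default 55) training patients and the rest as test; the
foreign model is fitted once (it does not depend on the split). Each
repetition r draws its split from a generator seeded `seed + r`, making
runs reproducible and parallelisable. Repetition-level fit failures
(e.g. separation on a 55-patient split, where a rare histology level can
have no events) are recorded as NaN with the reason kept; the run aborts
if fewer than 90% of repetitions succeed. Correlations are Pearson (a
Spearman flag exists for sensitivity analysis but is never the default).

A structural fact worth stating: per-gene *mean* batch shifts cannot move
any of these correlations, because univariate Cox screening, Cox
coefficients and Pearson correlations of linear predictors are all
invariant to covariate location shifts. What degrades gene-model
transferability in practice — and in this package's tests — is signature
instability: under a weak, diffuse gene signal, different 55-patient
training splits select different genes, and ρ₁/ρ₃ fall well below 1
while clinical models stay stable.

## Synthetic-data generator

Each patient carries a latent risk factor U ~ N(0,1). Planted prognostic
genes are loading·U + N(0, noise_sd) (defaults 1.0 and 0.5); the rest of
the panel is N(0,1) noise. Clinical covariates: age ~ N(63, 10) clipped
to [30, 88]; gender Bernoulli(½); AJCC stage 1–4 obtained by cutting a
normal correlated with U (correlation 0.4) at quantiles giving marginal
probabilities 0.35/0.30/0.20/0.15 — so stage genuinely carries prognostic
information and clinical models have signal; histology with three levels
(0.5/0.3/0.2) and no effect by default. The true linear predictor is the
exact dot product of the generating coefficients with the raw covariates
(defaults: 0.02 per year of age, 0.10 for male gender, 0.45 per stage
unit, 0.05 per planted gene), so it is recomputable from the stored
tables.

Event times are exponential with hazard `baseline_hazard_rate · exp(score)`
(default 0.001/month, giving a median around 5–6 years at typical covariate
values); the Cox model is baseline-agnostic, and the constant baseline
gives closed-form checks (median event time ln 2/λ at score 0, exact
Kolmogorov–Smirnov reference). Censoring is an independent exponential
(default 0.008/month) truncated by an administrative cutoff at 120
months, yielding a censoring fraction around 40–50%, typical of registry
cohorts; `censoring_rate_for_fraction` computes the rate for a target
fraction analytically. Per-center batch effects add a per-gene mean shift
drawn N(0, batch_shift_sd) to the stored expression *after* outcomes are
drawn: batch effects perturb what a model sees, never the truth. (The
shift adds a per-center constant β·shift to stored-data dot products;
`GroundTruth.center_offsets` records it so the true scores remain exactly
recomputable.) All random draws are taken unconditionally and scaled, so
two configurations differing only in a rate share the rest of their
random stream.

The default center layout (4 centers of 177/79/82/104 patients) mirrors a
four-center lung consortium cohort; the default panel of 1,000 genes with
20 planted prognostic genes is a desk-scale stand-in for a genome-wide
array. What the generator does **not** emulate: probe-level microarray
structure and normalisation artifacts, correlated noise between
non-prognostic genes, non-proportional hazards, competing risks,
time-varying covariates, and informative censoring. Passing tests
therefore demonstrate correctness of the estimators and the cross-center
machinery under a proportional-hazards world, not robustness to those
real-data violations.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the framework at reduced
scale chosen to exercise every code path with comfortable margins:
4 centers × 150 patients for table-structure checks, 2 × 250 with 55/rest
splits and 50–100 repetitions for resampling, n = 1000 × 100 replicates
for parameter recovery, n = 2000–5000 for generator calibration, and
60–200-gene panels. These sizes are the package's own verification
conditions; the library itself has no such limits.

## Known limitations

* The Cox fitter handles moderate p (tens of covariates), not
  high-dimensional fits; gene models reduce dimension before fitting by
  design, and no penalised or cross-validation-tuned selection is
  provided (deliberately out of scope).
* The survival tree is a single tree with greedy log-rank splits; no
  pruning, no ensembles.
* Somers' D_xy uses O(n²) pair enumeration — fine up to a few thousand
  patients per cohort, the regime this framework targets.
* Confidence intervals for D_xy and the correlation statistics are not
  provided; the resampling distributions serve that role for ρ₁/ρ₂/ρ₃.
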