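# Methods

`hteforest` implements a workflow for discovering heterogeneous treatment
effects (HTE) in two-arm randomised controlled trials with a binary
outcome, and for converting the discovered heterogeneity into a clinically
actionable subgroup threshold. This note records the models, the
estimators, the defaults, and the design decisions that were genuinely
open, in the package's own terms.

## Estimands

With potential outcomes Y(1), Y(0), treatment W ∈ {0,1} and baseline
covariates X, the conditional average treatment effect is

    τ(x) = E[Y(1) − Y(0) | X = x],

which in a randomised trial equals E[Y|W=1,X=x] − E[Y|W=0,X=x]. A group
average treatment effect (GATE) is the mean of τ over a subgroup, here
always defined by thresholding one continuous covariate.

## Synthetic trial generator

The generator emulates a sepsis trial in which the benefit of the
experimental vasopressor reverses above a serum-potassium threshold:

* W ~ Bernoulli(0.5);
* X1 ~ N(0,1), prognostic only;
* X2 ~ N(4.58, 0.937²), in mmol/L, matching the observed distribution of
  maximum serum potassium in the motivating trial's baseline table;
* latent subgroup S = 1{X2 > 4.68} (strict inequality);
* Y ~ Bernoulli(expit(β0 + β_X1·X1 + β_W·W + β_WS·W·S)), Y = 1 meaning
  alive at day 28.

β_X1 defaults to 0.5 log-odds per SD — a moderate prognostic signal chosen
so the outcome forest has something real to learn; it is exposed in
`DGPConfig`. The remaining coefficients are *calibrated*: because X1 ⊥
(W, S), each marginal target reduces to a one-dimensional root of a
128-node Gauss–Hermite integral, solved sequentially for β0 (control-arm
survival 72.5%), β_W (risk difference +0.069 below the threshold) and
β_WS (risk difference −0.257 above it). Re-simulation at n = 10⁶ recovers
all three targets within 0.005. Infeasible targets (an implied survival
outside (0,1)) fail with the violated target named.

What the generator does **not** emulate: longitudinal daily measurements,
informative missingness tied to illness severity, competing risks, or the
correlation structure of real ICU covariates. A separate mixed-type
generator (`generate_vanishlike`) produces continuous/binary/categorical
baseline tables with requested missingness (MCAR or MAR on an observed
column) and pairwise correlations through a Gaussian copula; it exists to
exercise the preprocessing code, not to carry effect signal. Passing tests
on these fixtures shows the machinery is correct under its stated
assumptions, not that the pipeline is robust to real-data pathologies.

All randomness flows through the PCG64 bit generator; replicate seeds are
spawned by counter from a root seed (`numpy.random.SeedSequence`), so
study results are independent of execution order and of serial vs.
parallel scheduling.

## Preprocessing

1. Covariates with ≥ 30% missing entries are dropped (only columns with
   < 30% missingness are candidate modifiers; the boundary case is
   dropped).
2. For every pair with |Pearson r| > 0.7 (pairwise-complete), the member
   carrying less information is dropped: higher missingness first, then a
   declared derived-score flag, then the later column. Pairs are visited
   in decreasing |r| (greedy), skipping columns already removed.
3. Categorical columns are one-hot encoded keeping **all** levels — the
   downstream consumers are penalised or tree-based, so the redundancy is
   harmless; continuous columns are centred and scaled using the sample SD
   (ddof = 1) of observed values, with original mean/SD stored so learned
   thresholds can be reported in raw units.
4. Remaining missingness is handled by one of: iterative random-forest
   imputation (variables visited in order of increasing missingness;
   stops the first time the summed normalised discrepancy between
   successive imputations rises, returning the previous iterate; 100
   trees, seeded); mean/mode imputation; complete-case deletion; or
   inverse-probability-of-completeness weighting. The IPW completeness
   model is a logistic regression on the treatment, the outcome and all
   fully observed covariates (the choice of predictors was open; using
   every fully observed column is the least arbitrary default).
   Estimated completeness probabilities below 0.01 are truncated at the
   1st percentile with a recorded warning.

## Univariable interaction screen

For each covariate X_k a separate logistic model
logit E[Y|W,X_k] = b0 + b1 W + b2 X_k + b3 W·X_k is fitted by maximum
likelihood (an intercept is always included) with a Wald test of b3.
Family-wise error over the K screens is controlled by Bonferroni (α/K);
Benjamini–Hochberg flags are computed alongside for volcano-plot
colouring. Separation or non-convergence yields a `converged=False`
sentinel with an infinite CI rather than an exception or a penalised
fallback, so simulation power tallies are not contaminated by a different
estimator.

## Hierarchical interaction lasso

The joint model contains the treatment, all main effects, and all
treatment-by-covariate interactions. Strong hierarchy
(b3_k ≠ 0 ⇒ b2_k ≠ 0 and b1 ≠ 0) is enforced by an overlapped-group
(latent) parameterisation: an unpenalised intercept, L1-penalised
singleton copies of the treatment and each main effect, and one
three-member group per covariate containing latent copies of the
treatment effect, the covariate main effect, and the interaction. An
interaction can only enter through its group, which activates its main
effects with it. Interactions are restricted to treatment × covariate
pairs (the scientific question is effect modification, not general
epistasis).

Groups carry weight √3 (the √(group size) convention). This was a
genuinely open choice: with *unit* group weights the three-member groups
have ≈ √3-larger null-gradient norms than the singletons, so under pure
noise an interaction is the first term to activate and the null
false-retention rate of the selector is badly inflated; the √(size)
weights restore the expected behaviour (≥ 90% of pure-noise datasets at
n = 500 with ten covariates keep no interaction).

The penalised mean negative log-likelihood is minimised by monotone
proximal-gradient descent with backtracking line search; a geometric
50-value λ path runs from λ_max (the smallest penalty with all groups
zero, computed from the gradient at the intercept-only fit) down to
0.001·λ_max with warm starts, stopping at relative objective change
< 1e−7. At λ → 0 the solver agrees with the unpenalised MLE to < 1e−3.
λ is selected by 5-fold CV, stratified by outcome, minimising mean
held-out binomial deviance per observation (the CV metric was unstated in
the source material; deviance is the standard choice for penalised
logistic models). Ties resolve to the stronger penalty. Continuous
covariates must arrive centred and scaled (enforced), so coefficient
magnitudes are comparable as standardised (log-)odds ratios.

"Significance" of a retained interaction is assessed by an unpenalised
logistic refit on the selected support with a Wald test — a deliberately
naive, clearly labelled mechanism (`naive_refit_wald`): the same data
chose the support, so these p-values are optimistic and are used only as
a detection rule inside simulations, never as confirmatory inference.
Polyhedral/selective inference is out of scope. A term the lasso did not
retain is a defined "not selected" outcome and counts as non-detection.

## Honest causal forest

Nuisances. p(X) = E[W|X] and m(X) = E[Y|X] are estimated by regression
random forests (Y-forest never sees W) with out-of-bag predictions, so no
participant's nuisance value uses trees trained on them. The leaf size of
each nuisance forest is selected from {5, 25, 125} by OOB error using
small pilot forests, with the constant (mean) predictor competing under
leave-one-out error. This selection matters: an under-smoothed treatment
forest partially memorises W, leaving negatively correlated residuals
that inflate the omnibus test's type-I error well above nominal; for a
randomised W the selection collapses to (near-)constant propensities
automatically. Propensities are clipped to [0.01, 0.99]; for randomised
designs `fix_propensity=0.5` is available.

Trees. Each of B trees is grown on a without-replacement subsample of
fraction 0.5, split half/half into a grow half and an estimate half
(honesty). On the grow half, splitting is greedy: at each node `mtry`
candidate variables are drawn, candidate thresholds are midpoints between
consecutive distinct sorted values, child effects are the residual ratios
τ_c = Σ(w_resid·y_resid)/Σ(w_resid²), and the selected split maximises

    n_L · n_R · [ (τ_L − τ_R)² − κ·(V̂_L + V̂_R) ],

where V̂_c are sandwich variance estimates of the child ratios and
κ = `variance_penalty` (default 1; κ = 0 recovers the plain squared-
contrast criterion). The penalty exists because
E[(τ̂_L − τ̂_R)²] = (τ_L − τ_R)² + V_L + V_R: the raw criterion's
expectation is inflated exactly where children are small and noisy, and
under the calibrated DGP this visibly skews root thresholds upward (the
noisier high-potassium side attracts the argmax) even with oracle
nuisances; subtracting the estimated variance terms removes the
expectation bias. Splits also require each child to hold ≥ 5% of the
parent's rows (`balance_fraction`, mirroring the reference forest
implementation's default imbalance limit), ≥ `min_node_size` = 5 rows,
and ≥ 1 participant of each arm. A node where no admissible split has a
strictly positive score becomes a leaf. After growing, estimate-half rows
are routed down the tree; a leaf left empty of estimate rows is collapsed
into its sibling.

Defaults: B = 2000 for single-dataset analyses, B = 500 inside
simulations; mtry = min(K, ⌈√K⌉ + 3); all recorded on the fitted model.

CATEs. For participant i, the out-of-bag CATE aggregates, over exactly
those trees whose subsample excluded i, the leaf-mean contributions of
the estimate halves: τ̂(x) = Σ_i α_i(x)(W_i−p̂_i)(Y_i−m̂_i) /
Σ_i α_i(x)(W_i−p̂_i)², with α the leaf-size-normalised co-membership
frequencies. Per-point confidence bands (bootstrap-of-little-bags) are
out of scope; the OOB CATE distribution is exported instead.

Omnibus test. With τ̄ the mean OOB CATE, the outcome residual is
regressed without intercept on A_i = τ̄·w_resid_i and
D_i = (τ̂_i − τ̄)·w_resid_i. The coefficient on D is the differential
forest prediction (DFP; ≈ 1 indicates well-calibrated heterogeneity) and
its one-sided HC3-robust p-value tests for the presence of heterogeneity.
Under the homogeneous-effect DGP the rejection rate at α = 0.05 sits
inside [0.03, 0.08] across 500 replicates of the default pipeline.

Variable importance. importance(j) ∝ Σ_{d=1..4} (fraction of depth-d
splits on j) · d^(−2), normalised to sum to one; depth cap and decay
exposed as arguments since the reference formula's exact constants are
not public.

AIPW. Doubly robust scores
Γ_i = τ̂_i + (W_i−p̂_i)/(p̂_i(1−p̂_i)) · (Y_i − m̂_i − (W_i−p̂_i)τ̂_i);
a GATE is the subgroup mean of Γ with SE = SD/√n and a normal 95% CI.
Because the same data fitted the forest, these intervals can understate
uncertainty; every GATE result carries a standing warning to that effect.

## Root-split subgroups

Each tree's root split maximises the between-half effect contrast, so the
most common root variable across the forest is the dominant first-order
effect modifier. The summary tallies root variables (one-hot levels are
tallied under their parent categorical), takes the modal variable (ties
break to the lower column index, flagged), and averages its root
thresholds **on the raw scale** (back-transforming through stored
standardisation parameters) — the mean, per the source procedure, with
the median available as a robustness option. The population is then
partitioned at the mean threshold (low: ≤, high: >) and each side's GATE
estimated from the AIPW scores. No valid inference is claimed for the
threshold itself; this is a hypothesis-generation device.

## Simulation study (ADEMP)

*Aims*: how often does root-split extraction identify the true modifier,
and how accurately does the mean root threshold recover the true 4.68?
*Data*: replicates of n = 1000 from the calibrated DGP. *Estimands*: the
modal root variable and mean threshold; comparator detection rates.
*Methods per replicate*, all on identical data: causal forest (B = 500,
nuisance forests of 200 trees) + root splits + omnibus test + subgroup
GATEs; univariable interaction tests with X2 continuous and with X2
dichotomised at the deliberately wrong clinical threshold 5.4; the
hierarchical lasso in both codings with the post-selection detection
rule. *Performance*: % modal-correct, mean/SD/MSE and 2.5–97.5 percentile
range of per-replicate mean thresholds (MSE in population form, so
MSE = SD²(n−1)/n + bias² holds exactly), and detection percentages, each
with a binomial Monte-Carlo SE.

The default harness runs 100 replicates (the full-size study of 1000 is
one flag away); with B = 500 trees per forest this keeps a complete study
within a coffee break on one core while leaving Monte-Carlo SEs around
1–4 percentage points. Method failures inside a replicate are recorded as
sentinels and never abort the study.

## Numerical choices and degenerate inputs

* Thresholds are midpoints of consecutive distinct values, so every
  stored threshold lies strictly between two observed grow-half values;
  a value exactly at a reported threshold goes to the low side.
* Residual-ratio denominators: a candidate child with Σ(w_resid²) = 0 is
  inadmissible; clipped propensities bound the AIPW factor.
* Constant OOB CATEs make the DFP regression degenerate; the test returns
  a defined "no heterogeneity detected" outcome.
* The proximal solver is monotone by construction (backtracking step
  halving with a descent safeguard); λ path endpoints were checked
  against closed forms (all-zero at λ_max, MLE at λ → 0).
* Forests with fewer than 10 trees are refused: OOB weights would be too
  sparse to define per-row CATEs.

## Known limitations

* The threshold estimator remains mildly right-skewed per tree even with
  the variance penalty; averaging over 500 roots per replicate leaves a
  small (+0.03 to +0.05) mean bias under the calibrated generator. No
  uncertainty statement is attached to the threshold.
* Post-selection lasso p-values are optimistic by construction.
* AIPW GATE intervals reuse the data that fitted the forest.
* IPW weights propagate to the univariable screen but not to the lasso
  (the penalised objective has no weighted variant here; a recorded note
  is attached when weights are dropped).
* Competing-risk outcomes and clustered designs are unsupported.
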