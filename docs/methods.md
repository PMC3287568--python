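# Methods

This note documents the models and procedures implemented in `plsprog`,
the parameters that matter, the numerical choices, and what the synthetic
testbed does and does not establish.

## Problem setting

The package targets binary recurrence prognosis from expression matrices
in the p ≫ n regime: a few hundred patients, tens of thousands of probes,
and right-censored time-to-recurrence. Class labels are derived from the
clinical table at a cutoff c (months): a patient with an observed
recurrence at time ≤ c is high risk (+1); a patient known recurrence-free
past c (event or censoring after c) is low risk (−1); a patient censored
at or before c has an unknowable class and is excluded from both training
and evaluation. Raising c can only move patients into, never out of, the
high-risk class.

## Data cleaning

Probes with no observed value in any sample are dropped; probes missing
in some samples have those cells imputed with the probe's mean over the
observed samples (leaving the probe mean unchanged). Accepted missing
markers are `NA` and empty cells. Orientation of expression files
(probes-as-rows vs samples-as-rows) is auto-detected from a `probe_id`
header field or a majority of `_at` row identifiers and can be forced.
Clinical covariates (age, gender, stage) can optionally be appended as
three extra feature columns — gender as 0/1, stage as ordinal integers,
both standardized downstream with every other column; default off
(`use_covariates`).

## Coarse Feature Reduction

Stage 1 keeps probes whose pooled-variance two-sample *t*-test between
classes has p < `p_cutoff` (default 0.05; Welch available by flag). A
zero-variance probe has an undefined statistic and is dropped. Stage 2
keeps, of those, probes with coefficient of variation sd/|mean| ≥
`cv_cutoff` (default 0.632), i.e. it prunes low-variability probes; a
probe with exactly zero mean gets CV = +∞ (kept, with a warning), and a
`direction` flag inverts the comparison for data where low CV is the
interesting regime. Under null data the stage-1 retention is calibrated
at the α level, which the acceptance suite verifies within a 99%
binomial band.

## Partial least squares

Fitting happens on standardized data: training columns to mean 0, sd 1
(constant columns get scale 1 and a warning), response centered and
scaled; validation folds always reuse training statistics. Deflation
follows the classical scheme: w_m = X_mᵀy_m, t_m = X_m w_m normalized,
X and y deflated by the rank-one explained component, y renormalized
after deflation. The renormalization only rescales the next weight
vector; it is kept because β = W(TᵀXW)⁻¹Tᵀy — evaluated with the
*original* centered X, y — is invariant to positive rescaling of W's
columns (a tested identity). Fitted values equal the projection of y onto
span(T), so training R² is non-decreasing in M and the fit coincides
with OLS at M = rank(X); predictions match scikit-learn's NIPALS PLS1 to
machine precision on random problems.

Numerical choices: M must satisfy 1 ≤ M ≤ min(n−1, p); deflation is
declared exhausted when ‖t_m‖ < 1e-10·‖X‖_F (error names the offending
latent variable); a singular TᵀXW raises a numerical error rather than
being regularized. Loadings p_s = t_sᵀX_s and q_s = t_sᵀy_s are stored as
diagnostics only — β does not need them.

## Kernels and K-PLS

Four kernels: dot product u·v; polynomial (u·v+1)^d on unit-normalized
inputs (auto-normalization on by default, a strict mode rejects non-unit
inputs), bounded by 2^d; Gaussian RBF exp(−‖u−v‖²/2σ²); exponential RBF
exp(−‖u−v‖/2σ²). The exponential form divides the *unsquared* distance
by 2σ², which is not the common exp(−d/σ) parameterization — σ values
are not transferable between the two conventions.

The training Gram matrix is double-centered, K₁ = (I−𝟙𝟙ᵀ/n) K₀
(I−𝟙𝟙ᵀ/n); test blocks are centered with the training row means and
grand mean, the exact kernel-space analogue of applying training
standardization to validation data. K-PLS iterates t_m = K_m y_m
(normalized), two-sided kernel deflation, and y deflation/renormalization
with y standardized to mean 0, sd 1. Dual coefficients are
a = U(TᵀK₁U)⁻¹Tᵀy with U collecting the pre-deflation responses;
predictions are f(x) = Σ K₁(xᵢ,x)aᵢ, un-standardized on output. This is
the standard dual form; it reduces exactly to linear PLS under the dot
kernel for every M, the identity used as the primary oracle, and
predictions are invariant to adding a constant to all raw kernel values
(absorbed by centering).

## Fine Feature Selection

Each of R runs draws a stratified random training fold (default 2/3,
configurable) and ranks features by |w₁| of a one-latent-variable PLS on
that standardized fold — the sign of a weight carries no importance
information. In setting l ∈ {20, 30, 150}, the rank-r feature (r ≤ l)
scores l − r + 1; per-setting scores accumulate over runs and sum to
l(l+1)/2 per run. The top p features per setting (ties broken by original
feature order, making retention deterministic) form S_lᵖ, and the final
set is the union S_FFSᵖ, with p ≤ |S_FFSᵖ| ≤ 3p. The retention size p is
chosen by the model-selection grid (default grid 50…550 in steps of 50,
truncated to the CFR set size). The reference run count is R = 10,000;
the test and acceptance suites use R between 25 and 200, which already
recovers planted features essentially perfectly at the simulated effect
sizes — the statistic is an average, so R trades Monte-Carlo noise for
time without changing its expectation.

## Evolutionary-programming kernel search

Candidates hold object parameters γ (log₁₀ σ, degree, M) with positive
per-parameter strategy values v and a categorical kernel-family gene.
Mutation is self-adaptive: v′ᵢ = vᵢ·exp(N/√(2m) + Nᵢ/√(2√m)) with one
shared and one per-parameter normal draw (the log-sd of this update,
√(1/2m + 1/2√m), is Monte-Carlo-verified), then γ′ᵢ = γᵢ + Cᵢ·v′ᵢ with
standard Cauchy steps whose heavy tails produce occasional long jumps;
bounds are clipped and integer genes rounded after mutation; the family
is re-drawn uniformly with probability 0.1. Selection doubles the
population by mutation, scores everyone (a failing objective yields −∞
fitness), and keeps the top half by wins against q random opponents
(fitness breaks ties). Defaults — population 20, 50 generations, q = 10,
initial v at a tenth of each gene's range — are this package's choices;
fitness is mean cross-validated AUC with hierarchically derived seeds so
the whole search is reproducible.

## Evaluation protocol

AUC is the Mann–Whitney statistic (ties half credit), checked against an
exhaustive pair count and scikit-learn. Cross-validation is stratified
k-fold (default k = 5); leave-one-out pools held-out scores into a single
AUC. Two protocols are exposed:

* **paper** (default): CFR and FFS run once on the full labeled data,
  and the grid of (family, M, p) cells is then cross-validated on the
  selected features. This reproduces the classical protocol for this
  method family; because selection has seen all labels, its AUCs carry
  selection optimism and should be read as model-comparison scores, not
  unbiased generalization estimates.
* **nested**: CFR + FFS re-run inside every training fold. On null data
  this protocol is calibrated at AUC 0.5 (tested); it is the honest
  estimate and the appropriate default when the absolute AUC matters.

Model selection takes the grid argmax of mean validation AUC, breaking
ties toward fewer latent variables, then smaller p. On linear synthetic
data the chosen M concentrates on 1–3.

## Survival statistics

Kaplan–Meier curves use the product-limit estimator over distinct event
times; on uncensored data this is exactly the empirical survivor
function. Curve comparison uses the standard unweighted log-rank test
(hypergeometric expectation and variance per event time, chi-square with
1 df). The two-group Cox model maximizes the partial likelihood by
Newton–Raphson from β = 0 (tolerance 1e-12, at most 100 iterations);
Breslow tie handling is the default because it makes the score test at
β = 0 algebraically equal to the log-rank statistic on tie-free data (a
tested equivalence); Efron is available and matches lifelines to 1e-6.
The standard error comes from the observed information; the 95% CI is
exp(β̂ ± 1.96·se). |β| > 50 or vanishing information raises a divergence
error naming complete separation. p-values below 1e-15 are reported as
"<1e-15". Predicted prognosis groups are formed by thresholding
classifier scores at 0 on the ±1-coded scale (configurable).

## Synthetic testbed

The generator plants two latent risk classes: informative probes get a
mean shift of `effect_size · noise_sd` in the high-risk class; all other
probes are class-independent Gaussian noise around a baseline of 1.0
(with unit noise this puts probe CVs near 1, so default variance pruning
does not wholesale-delete simulated probes). Recurrence times are
exponential with class-specific hazards and independent exponential
censoring; survival depends on expression only through the class, so the
classifier → KM/Cox chain has analytically known behavior. Defaults
emulate a multi-institution adenocarcinoma cohort at the scale the
package targets: 300 samples × 20,000 probes, 50 informative, 40% high
risk, hazards 0.08 / 0.02 events·month⁻¹ (hazard ratio 4, median times
≈ 8.7 / 35 months), censoring hazard 0.01 month⁻¹. Tests use smaller
cohorts (e.g. 200 × 1000) to keep runtimes in seconds.

What the testbed does *not* model: probe-level intensity distributions,
batch/institution effects, correlated probe blocks, non-proportional
hazards, and any direct expression–time dependence within a class.
Passing tests therefore demonstrate correctness and calibration of the
machinery, not clinical performance on real cohorts. One structural
consequence worth knowing: because exponential times are memoryless, a
sizeable fraction of low-risk patients still recur before the cutoff, so
cutoff-derived labels are intrinsically noisy versions of the planted
classes; the honest (nested) AUC against those labels is bounded well
below 1 even for a perfect classifier, while the default paper-protocol
AUC is higher partly through selection optimism. The two protocols
bracket real behavior, which is why both are exposed.

## Known limitations

Single-response PLS only (no multi-column Y, no orthogonalized
variants); no low-rank kernel approximations (Gram matrices are n × n);
the Cox model is strictly two-group (no continuous or multivariate
covariates, no time-varying effects); TOML configs are flat key/value
blocks; CEL-file parsing and upstream normalization are out of scope —
inputs are assumed already normalized expression values.
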