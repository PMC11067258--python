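# Methods

## Estimands and weights

The package estimates weighted average controlled differences (WACDs)
between a minority group (`Z = 1`) and a majority group (`Z = 0`), with
covariates split into SES variables `xˢ` (categorical) and health-status
variables `xʰ` (numeric after dummy-encoding). Writing `e(x)` for the full
propensity score and `e(xˢ)` for the SES-only score, a tilting function
`g(e)` fixes the target population:

| estimand | g(e)    | target population |
|----------|---------|-------------------|
| ate      | 1       | combined          |
| att      | e       | minority          |
| ato      | e(1−e)  | overlap           |

Balancing weights `ω₁ᴮ = g(e)/e`, `ω₀ᴮ = g(e)/(1−e)` tilt both groups
toward `g(e(x))f(x)`. The deweighting weights are the ratio of full-PS to
SES-PS balancing weights, `ω_z = ω_zᴮ(x)/ω_zᴮ(xˢ)`. Weighting group `z`
with `ω_z` produces a population whose conditional health-status
distribution given SES is the common target `f(xʰ|xˢ)·g(e(x))/g(e(xˢ))`
while the marginal SES distribution remains that group's own — the
defining property of IOM concordance. Specializations: ATE →
`(e(xˢ)/e(x), (1−e(xˢ))/(1−e(x)))`; ATT → `(1, odds(e(x))/odds(e(xˢ)))`;
ATO → `((1−e(x))/(1−e(xˢ)), e(x)/e(xˢ))`. The implementation always
computes the general ratio; the ATT minority weight is pinned to exactly 1.

All estimators and diagnostics are Hájek (ratio) forms, so weights are
stored unnormalized and every result is invariant to rescaling either
group's weights.

## Propensity-score estimation

**SES-PS.** SES covariates are categorical, so the model with all main
effects and interactions is saturated and its ML fit is the subgroup
minority proportion `n1_r/(n1_r+n0_r)`. It is computed in that closed
form. A subgroup with no minority or no majority members is a positivity
violation and raises an error; nothing is clipped.

**Full PS.** Fitted separately within each SES subgroup with an intercept
plus health-status main effects (the SSHS-PS). Rationale: the quantity
that must be balanced is the conditional distribution of health status
given SES, and per-stratum fits give exact within-stratum balance
guarantees — with ML estimation the overlap (ATO) weights balance every
modeled covariate's weighted mean exactly (the score equations coincide
with the balance equations), and just-identified CBPS extends exact mean
balance to the ATE and ATT tilts.

**CBPS solver.** The just-identified variant is implemented (the
diagnostics of interest show near-exact balance, which is the defining
property of this variant; the over-identified variant is out of scope).
The balance systems

- ATE: `(1/N) Σ [Z/e − (1−Z)/(1−e)] x = 0`
- ATT: `(1/N) Σ [Z − (1−Z)·e/(1−e)] x = 0`

are gradients of strictly concave potentials in the logistic coefficients
(`Σ[(2Z−1)η − Z·e^{−η} − (1−Z)·e^{η}]/N` and `Σ[Zη − (1−Z)e^{η}]/N` with
`η = xβ`), so the solver is Newton ascent on the potential with Armijo
backtracking, started at the ML solution, with internal column scaling for
conditioning. It converges globally whenever a root exists; tolerance
1e-8 on the max-norm of the mean-normalized residual, at most 200
iterations, and nonconvergence raises an error carrying the final
residual. For ATO the ML fit is returned unchanged (exact balance already
holds there). Linear predictors are clipped at ±600 inside exponentials
purely to avoid floating-point overflow during line search; the clip is
never active at an accepted solution of a well-posed problem.

**ML fits** use IRLS (statsmodels GLM/binomial, tolerance 1e-10). Rank
deficiency is detected beforehand by pivoted QR and reported with the
collinear column names. Perfect separation is detected from the fitted
probabilities (all minority fits > 1−1e-8 and majority fits < 1e-8) or
from the solver's own failure, and raises. Columns constant within a
stratum are dropped from that stratum's design (they are trivially
balanced there); the drop is recorded in the per-stratum convergence log.
An opt-in fallback scores a stratum whose fit fails by a pooled
main-effects model, logged; by default such strata raise.

**Positivity.** Fitted probabilities must lie strictly in (0, 1); values
within 1e-6 of the boundary trigger a warning naming the count of affected
subjects. No trimming or truncation is performed by default.

## Estimation and uncertainty

The disparity estimate is the difference of within-group Hájek means of
the outcome. Variances use Taylor linearization of each Hájek mean with
weights treated as fixed, groups independent:
`Var(τ̂) = Σ w²(Y−μ̂)²/(Σw)²` summed over the two groups, with normal
quantiles for the interval (not t). This matches the behaviour of standard
survey software; uncertainty from propensity-score estimation is *not*
propagated — a deliberate choice, consistent with common practice, and the
coverage test below measures its practical effect. A subject-resampling
bootstrap (within group, weights travelling with subjects) is provided as
a cross-check; at n = 2000 it agrees with the linearization SE to within
10%. With unit weights the variance reduces to the n-divisor two-sample
formula. Binary outcomes are reported in percentage points (×100); the
raw scale is kept internally.

## Balance diagnostics

All four metrics use *unweighted* standard deviations (ddof = 1) in the
denominator, so the yardstick does not move with the weights:

- `D`: |weighted minority mean − weighted majority mean| over the pooled
  unweighted group SDs;
- `D₁`, `D₀`: |unweighted − weighted own-group mean| of each SES covariate
  over that group's own unweighted SD;
- `D_r`: the `D` form restricted to SES subgroup `r`, for health
  covariates, with pooled unweighted within-subgroup SDs.

Binary covariates enter as numeric 0/1. Zero-SD denominators yield a
metric of 0 with an explicit `degenerate` flag (a constant covariate
carries no imbalance information and must not crash a batch report).
`D_r` cells where either group has fewer than two subjects in the
subgroup are flagged `insufficient_n`, reported as NaN, and excluded from
threshold flagging. The flagging threshold defaults to 0.1, the
conventional imbalance cut; any exceedance marks the weight set as not
IOM-concordant.

## Synthetic generator and oracle

The generator draws `Z`, then an SES cell from a race-specific joint
table, then health covariates from a multivariate normal whose mean is
shifted additively by race and by each SES variable (common covariance),
then a Bernoulli outcome from a logistic model in all three. Defaults are
chosen to mimic the *shape* of the right-heart-catheterization
application, not its values: 17.1% minority share; two binary SES
variables with race-specific joint tables matching that study's SES
marginals (education ≥ high school 18.6% vs 30.4%, income ≥ $25K 11.6% vs
25.8%) with positive education-income association; K = 6 health covariates
with AR(1) correlation 0.3, race shifts up to 0.4 SD and SES shifts up to
0.3 SD; outcome intercept −0.35, race coefficient −0.15, SES coefficients
(0.35, 0.30), giving ≈46% prevalence. Every SES cell has positive
probability under both races, so positivity holds by construction. All
randomness flows through a single seeded NumPy generator.

Because the factorization is explicit and the health covariance is shared,
both true propensity scores have closed forms (Bayes' rule; the full-PS
log-odds are linear in `xʰ` with stratum-specific intercepts — so the
stratified main-effects PS model is correctly specified). The oracle
evaluates each estimand by weighting *true* conditional outcome means with
weights built from *true* propensities on a large simulated population
(default 10⁶ draws), reporting the linearization Monte-Carlo SE; no fitted
model enters the oracle path.

What the generator does not emulate: real clinical data have skewed and
discrete health measurements, misspecified propensity models, missing
data, and SES categories finer than binary. Passing tests therefore
demonstrate the algebraic and statistical properties of the method under a
correctly specified, well-behaved data-generating process — not robustness
to the failure modes of real data.

## Problem sizes used in the checks

Exact-balance identities are checked at n = 2000; estimator-vs-oracle
recovery at n = 10⁵ against a 10⁶-draw oracle; interval coverage over 500
replicates at n = 2000 (ATT deweighting, the estimand whose minority
weights are exactly unit); the independence reduction at n = 10⁵. The
acceptance script evaluates the SES-alteration diagnostic at n = 5000.

## RHC preprocessing recipe

The application recipe restricts the public right-heart-catheterization
table to black and white patients (Z = 1 for black), takes receipt of RHC
as the outcome, dichotomizes education at ≥ high school (years ≥ 12) and
income at ≥ $25K, and assembles 27 health-status columns: 20 continuous
variables (age, a comorbidity count constructed as the sum of the 12
binary history indicators, Duke activity index, APACHE and Glasgow coma
scores, vitals and baseline laboratory values, weight) plus sex, cancer
status, the primary disease category pooled to ARF/CHF/MOSF/Other, and
DNR status, each dummy-encoded with the most frequent level as reference
(1 + 2 + 3 + 1 dummies). The recipe is deterministic; reference levels are
logged. The public file is not redistributed — the user supplies its path —
and a clearly labelled synthetic stand-in with the same columns and level
codings exists solely to exercise the pipeline.

## Known limitations

- Only the three named tilts (ATE/ATT/ATO); no user-supplied `g`, no
  matching or entropy weights.
- No propagation of PS-estimation uncertainty into intervals (bootstrap
  offered as a cross-check); no doubly-robust augmentation.
- Per-stratum fitting needs adequate stratum sizes; with many SES cells or
  few subjects per cell the CBPS root may not exist and the fit raises
  (an opt-in pooled fallback exists). Model-selection machinery for that
  regime is out of scope.
- Missing data: fail by default, opt-in complete-case drop; no imputation.
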