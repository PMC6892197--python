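# Methods

## Estimands and notation

For participant *i*: exposure `A_i ∈ {0,1}` at baseline; survival to the
follow-up wave `Z_i`; attendance `R_i` (defined only for survivors); binary
outcome `Y_i` (defined only for surviving attenders); measured covariates
`V = (V1 sex, V2 mean-centred age)`. Potential values `Z_i(a)`, `Y_i(a)`
follow the usual counterfactual conventions, with `Y_i(a)` *undefined* —
not missing — when `Z_i(a) = 0`. Principal strata are the four values of
`(Z(0), Z(1))`; the survivor average causal effect is the outcome odds
ratio between exposure levels within the always-survivor stratum.

Identification assumptions shared by both estimators: no unmeasured
exposure–outcome confounding given `V`; outcome data missing at random
given `V` among survivors; positivity; one version of treatment and no
interference. The MSM additionally requires survival and attendance to be
correctly modelled by `(A, V)`; the sensitivity approach replaces that with
an explicit parameter τ for the compliant/always-survivor outcome contrast
and (for its τ = 1 closed form) the monotonicity assumption `Z(0) ≤ Z(1)`.

## MSM estimator

Propensities are logistic fits: exposure on `V` (all N), survival on
`(A, V)` (all N), attendance on `(A, V)` (survivors). The stabilized weight
for surviving attenders is

    W_i = SF_{A_i} / [ (A_i p_i + (1−A_i)(1−p_i)) · q_i · m_i ].

The stabilizing numerator is the within-arm mean probability of the
*observed* exposure level (`SF1 = mean(p | A=1)`, `SF0 = mean(1−p | A=0)`),
i.e. an estimate of `P(A = A_i)` — the standard construction; a
transcription-literal variant that averages `p` in both arms is available
behind `literal_eq6=True`. Weights are undefined for non-survivors and are
never truncated by default (`cap_percentile` opts in, with logging).

The final fit is weighted logistic regression of `Y` on `(A, V)` over
complete-case surviving attenders; adjusting for `V` on top of the weights
follows the doubly-protective convention for stabilized-weight MSMs. The
`A` coefficient is the SACE log odds ratio. Confidence intervals are
bias-corrected bootstrap: resample the N baseline rows, refit all models;
`z0 = Φ⁻¹(frac{θ* < θ̂})` with ties counted half each (avoiding `Φ⁻¹(0)` at
small B); endpoints are bootstrap quantiles at `Φ(2z0 ± z_α)`. Failed
resamples are dropped and counted; >10% failures flags the interval
unreliable. A non-collapsibility caveat: the V-adjusted weighted
coefficient is a covariate-conditional effect, while the SACE target is
marginal; with the modest covariate effects of the default generator the
gap is ≈0.002 on the log-OR scale, far below Monte-Carlo noise.

## Closed-form sensitivity estimator

Arm-specific logistic outcome models (`Y` on `V`, fitted per observed arm
on attenders) give predictions `h_i(a)` for **all** survivors, attenders or
not, under both exposure levels; one survival model (`Z` on `(A, V)`, all
N) gives `g_i(a)`. Marginal quantities:

    ξ_a = (1/n_{Z=1}) Σ_{survivors} g_i(a) h_i(a),
    ν_a = (1/N) Σ_{all} g_i(a)          (default),

with a `nu_population="survivors"` switch for the strictly composite
reading in which both averages run over survivors. The default follows the
definition of ν_a as a *marginal* survival probability of the baseline
population; ξ_a is kept survivor-averaged as printed in the source method.
Both options are exposed because the original derivation leaves the
averaging population ambiguous; the difference is second-order in the
resulting odds ratio because ξ appears in numerator and denominator.

Given τ > 0, SACE_OR(τ) is the closed form with discriminant
`q = sqrt{[(ν0+ξ1)(1−τ)+τν1]² + 4ξ1ν0(τ−1)}`; within |τ−1| ≤ 1e−8 the
τ = 1 reduction `ξ1(ν0−ξ0)/(ξ0(ν1−ξ1))` is used instead, avoiding 0/0.
For τ < 1 numerator and denominator of the quadratic factor are both
negative; validity is checked on their ratio (the implied outcome odds
among exposed always-survivors), not on the parts. SACE_OR(τ) is
non-increasing in τ throughout the monotone-survival region ν1 ≥ ν0
(property-tested); estimates over a τ grid share one set of fitted models.

## Synthetic-cohort generator

The generator emulates a large ageing-cohort study: N = 10,000 per
replicate; binary sex, unmeasured genotype-like confounder `U`, and
unmeasured residence `D` all Bernoulli(0.5); age uniform on ±10 years
around its mean. Defaults (all config-overridable, units = log odds per
unit):

| model | intercept | exposure | sex | age | extra |
|---|---|---|---|---|---|
| exposure | −0.2 | — | 0.4 | 0.04 | — (U, D excluded by design) |
| survival | 0.8 | 1.3 | 0.3 | −0.03 | `alpha_UZ·(U−½)` |
| outcome | −2.4 | `beta_A` (calibrated) | 0.2 | 0.02 | `beta_UY·U` |
| attendance | 1.1 | 0.2 | 0.15 | −0.02 | `ln(0.5)·D` |

These give ≈50% exposure prevalence with clear baseline imbalance in sex
and age between arms, 77–81% survival (substantial death, and a
compliant-survivor stratum of ~20–25% — the SACE is the estimand of
interest precisely when exposure strongly affects survival), ~71%
attendance among survivors, and ~10% outcome prevalence among unexposed
survivors (rarer becomes unstable for logistic fits at this N). `alpha_UZ`
enters the survival model centred (`U − P(U=1)`) so that scenarios
differing only in the confounder's direction share the same marginal
mortality; disable with `center_survival_confounder=False`. Outcome
covariate effects are deliberately modest so the covariate-conditional and
marginal odds ratios nearly coincide (see the MSM caveat above).

**Potential survival coupling.** Under valid monotonicity, `Z(1) ~
Bernoulli(p1)` and `Z(0)` is drawn only among those with `Z(1)=1`, making
defiant-survivors impossible. Two conditional laws are offered:
`"conditional"` (default) draws `Bernoulli(p0)` within that subset — the
survival model evaluated at a=0, which concentrates always-survivors among
the jointly robust and is what reproduces the qualitative bias pattern of
the evaluation grid; `"marginal"` draws `Bernoulli(p0/p1)`, the unique
monotone coupling preserving the a=0 marginal `P(Z(0)=1) = p0` (its
marginal-preservation property is tested). Violated-monotonicity scenarios
draw `Z(0) ~ Bernoulli(p0)` independently for everyone.

**Potential outcomes** are drawn only where the matching `Z(a)=1`, from a
logistic model in `(a, V, U)`; a single uniform per participant thresholds
both `Y(0)` and `Y(1)` (common random numbers), leaving marginal laws
untouched while reducing the variance of within-cohort contrasts.

**Calibration of `beta_A`.** Odds ratios are non-collapsible and the
always-survivor composition shifts with `(alpha_UZ, beta_UY,
monotonicity)`, so the conditional exposure coefficient achieving a given
*marginal* always-survivor odds ratio (default 0.6) is re-solved per
scenario: one 10⁶-participant calibration cohort is drawn (covariates, U,
potential survival, strata); the objective compares the mean conditional
outcome probabilities over the realized always-survivor stratum at the two
exposure levels — the common-random-numbers objective with the binomial
noise integrated out — and Brent's method finds the root, with the bracket
widened twice before a calibration error. Residual tolerance 0.002 on the
log-OR scale. A fresh 10⁶ cohort then reproduces ln 0.6 within ±0.01 in
every grid scenario (tested).

**What the generator does not emulate.** Real cohorts have many correlated
covariates, non-logistic outcome processes, exposure measurement error,
informative missingness beyond a single residence indicator, and
multi-wave attrition. Passing tests demonstrate the estimators' behaviour
under the stylized mechanism — logistic everything, one binary unmeasured
confounder, single-wave attrition — not performance guarantees on real
data.

## Monte-Carlo study harness

Per replicate: simulate, record truth-table empirical SACE and empirical τ
(compliant- vs always-survivor odds of `Y(1)`), then estimate (1) MSM,
(2–4) sensitivity at τ = 1, 0.5, 2. Per scenario × method: mean estimate,
bias = mean − ln(target), empirical SE (SD of estimates, ddof=1),
MSE = bias² + SE², standardized bias = 100·bias/SE, and — when bootstrap
intervals are requested — coverage of the true log SACE (MSM only by
default, matching the evaluation convention). Replicate seeds derive from
`(base_seed, scenario_index, replicate)` via `SeedSequence`, so results are
reproducible and independent of `n_jobs` scheduling; degenerate replicates
(separation, zero cells) are excluded listwise per method with counts
reported, and a >5% failure rate flags the scenario metrics unreliable.
Presets: `paper` (1200 replicates, 1000 bootstrap resamples) and `desk`
(300/200).

Problem sizes used by the shipped checks: the acceptance script runs the
four no-outcome-confounding scenarios at full scale (1200 × N = 10,000
after 10⁶-participant calibration); the test suite runs the confounded
scenarios at 300 replicates, coverage at 200 replicates × 200 resamples,
and calibration recovery at 10⁶ — sizes at which every targeted effect
exceeds its Monte-Carlo noise while a complete run stays in the
ten-minute range on one CPU.

## Numerical choices

- Logistic fits: Fisher scoring with step-halving; convergence at
  max|score| < 1e−8 or relative deviance change < 1e−10, ≤100 iterations;
  singular information → error; coefficients beyond ±25 at "convergence"
  are treated as separation (a boundary maximum, not an MLE). Fitted
  propensities are defensively clipped to (1e−12, 1−1e−12) with a warning.
- Constant covariate columns are dropped from designs (collinear with the
  intercept); prediction designs replay the training-time column selection.
- Bias-corrected bootstrap: midrank tie handling in z0; degenerate
  (zero-spread) bootstrap distributions return a flagged zero-width
  interval.
- Undefined vs missing: both are NaN in memory, disambiguated by `Z` and
  `R`; on disk undefined is an empty CSV field and missing is the literal
  `NA`. Readers enforce that no outcome or attendance value appears for a
  non-survivor.

## Known limitations

- The MSM point estimate remains biased under any unmeasured
  survival–outcome confounder; the harness quantifies, not fixes, this.
- τ is assumed constant across covariate patterns; no elicitation tooling
  for plausible τ ranges is provided.
- Binary outcome and exposure only; single follow-up wave; no
  time-to-event or doubly-robust variants.
- The sensitivity estimator's ξ averaging follows the printed composite
  form; under strong survivor selection the "all" vs "survivors" ν options
  can diverge more than the default scenarios suggest — both are reported
  for audit.
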