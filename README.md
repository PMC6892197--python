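# sacekit

Estimation of the **survivor average causal effect (SACE)** for a binary
exposure and binary outcome when outcomes are *truncated by death* and
further *missing* because surviving participants do not attend follow-up —
the standard predicament of cohort studies of ageing (the motivating setting
is dietary exposure and late age-related macular degeneration, where both
death and non-attendance compete with outcome ascertainment).

Who it is for: biostatisticians and epidemiologists who need (a) SACE
estimates on real cohort tables, and (b) a reproducible simulation harness
for studying how unmeasured survival–outcome confounding biases those
estimates.

## The problem and the two estimators

Let `A` be a binary exposure, `Z` survival to the follow-up wave, `R`
attendance among survivors, `Y` the binary outcome (undefined — not merely
missing — for the dead), and `V = (V1, V2)` measured baseline covariates.
Principal strata classify participants by the joint potential survival pair
`(Z(0), Z(1))`: always-survivors (1,1), compliant-survivors (0,1),
defiant-survivors (1,0), never-survivors (0,0). The estimand is the odds
ratio among always-survivors,

```
SACE_OR = odds[Y(1)=1 | AS] / odds[Y(0)=1 | AS],
```

the only stratum in which both potential outcomes exist and exposure groups
remain exchangeable. Conditioning an analysis on observed survival opens a
collider path through any unmeasured common cause `U` of survival and
outcome — survival bias that no adjustment for measured covariates removes.

**Estimator 1 — marginal structural model (MSM).** Three logistic
propensity models (exposure `p_i`, survival `q_i`, attendance `m_i`, all on
measured covariates) combine into one stabilized inverse-probability weight
per surviving attender,

```
W_i = SF_{A_i} / [ (A_i p_i + (1-A_i)(1-p_i)) · q_i · m_i ],
```

with per-arm stabilizing constants `SF_a`. The exposure coefficient of the
weighted logistic regression of `Y` on `A` and `V` is the SACE log odds
ratio. Intervals are bias-corrected bootstrap (resampling baseline
participants, refitting everything).

**Estimator 2 — closed-form sensitivity analysis.** A sensitivity parameter

```
τ = odds[Y(1)=1 | CS] / odds[Y(1)=1 | AS]
```

encodes how compliant-survivors differ from always-survivors (τ = 1: no
survival bias). From arm-specific outcome models (fitted on attenders,
predicted for all survivors under both exposures) and a survival model, the
package computes marginal quantities ν_a = P(Z(a)=1) and
ξ_a = P(Z(a)=1, Y(a)=1) and evaluates SACE_OR(τ) in closed form — a
quadratic-root expression for τ ≠ 1 reducing to
`ξ1(ν0−ξ0) / (ξ0(ν1−ξ1))` at τ = 1. Reporting the curve over a grid of τ
turns an unverifiable assumption into a transparent sensitivity statement.

**Simulator and study harness.** `sacekit` also generates synthetic cohorts
with known principal strata, an unmeasured confounder `U` acting on survival
(log OR `alpha_UZ`) and outcome (log OR `beta_UY`), attendance-driven
missingness, and a per-scenario calibrated exposure coefficient so the true
SACE odds ratio is exactly a target (default 0.6). A 12-scenario Monte-Carlo
grid (`alpha_UZ ∈ {ln 0.5, ln 2}` × `beta_UY ∈ {ln 0.5, 0, ln 2}` ×
monotonicity valid/violated) measures bias, empirical SE, MSE, standardized
bias, and bootstrap coverage for each estimator.

## Worked example

```python
import numpy as np
import sacekit as sk
from sacekit.config import ScenarioConfig

cfg = ScenarioConfig()            # alpha_UZ=ln 2, beta_UY=0, valid monotonicity
beta_A = sk.calibrate_exposure_coefficient(cfg, n_calib=1_000_000)
cohort = sk.simulate_cohort(cfg, beta_A, np.random.default_rng(7))
obs = cohort.observed()           # analyst view: U, D, strata hidden

rec = sk.estimate_msm(obs, bootstrap_B=1000, seed=11)
sens = sk.sensitivity_curve(obs, tau_grid=(0.5, 1, 2))
```

Output for this seed:

```
beta_A = -0.5116
strata: {'AS': 6439, 'CS': 2543, 'DS': 0, 'NS': 1018}
MSM: OR=0.557 logOR=-0.584 CI=(-0.821, -0.356)
tau=0.5: OR=0.657  (nu0=0.635, nu1=0.898, xi0=0.0545, xi1=0.0448)
tau=1:   OR=0.559  (nu0=0.635, nu1=0.898, xi0=0.0545, xi1=0.0448)
tau=2:   OR=0.435  (nu0=0.635, nu1=0.898, xi0=0.0545, xi1=0.0448)
empirical SACE (truth table): -0.554
empirical tau (truth table):  0.986
```

Reading it: the calibrated conditional coefficient −0.512 yields a true
marginal SACE odds ratio of 0.6; on this N=10,000 replicate the truth-table
SACE is −0.554 (sampling noise). The MSM estimates OR 0.557 with a
bootstrap interval comfortably excluding 1. The sensitivity curve brackets
the effect across assumed survival-bias directions: protective everywhere,
stronger if compliant-survivors are assumed to carry *more* outcome risk
(τ = 2). At τ = 1 it agrees closely with the MSM, as it should when both
assume no residual survival bias. `nu0 < nu1` reflects the strongly
protective exposure effect on survival that creates the 25% compliant-
survivor stratum.

The same analyses run from the shell on any cohort CSV:

```sh
sacekit simulate --out cohort.csv --seed 7
sacekit estimate-msm --in cohort.csv --boot 1000 --seed 11 --out est.json
sacekit estimate-sensitivity --in cohort.csv --tau 0.5,1,2 --out sens.json
sacekit run-study --preset desk --out results/ --seed 2019
```

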