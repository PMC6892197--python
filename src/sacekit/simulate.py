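"""Principal-stratification cohort simulator.

Generates synthetic ageing-cohort data with truncation of the outcome by
death, attendance-driven missingness among survivors, and an unmeasured
binary confounder U acting on both survival (log OR ``alpha_UZ``) and the
outcome (log OR ``beta_UY``).  The conditional exposure effect on the
outcome, ``beta_A``, is calibrated per scenario so that the marginal odds
ratio of the outcome between exposure levels *within the always-survivor
stratum* — the survivor average causal effect — equals a target (default 0.6).

Generation order mirrors the natural causal ordering: covariates -> exposure
-> potential survival Z(0), Z(1) -> principal strata -> potential outcomes
Y(0), Y(1) (defined only where the corresponding Z(a)=1) -> attendance among
realized survivors -> observed outcome.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import AS, CS, PotentialCohort, assign_strata
from .config import MONOTONICITY_VALID, ScenarioConfig
from .errors import CalibrationError, ConfigurationError, DegenerateDataError

__all__ = [
    "generate_covariates",
    "generate_exposure",
    "generate_potential_survival",
    "generate_potential_outcomes",
    "generate_attendance",
    "assemble_observed",
    "simulate_cohort",
    "calibrate_exposure_coefficient",
    "empirical_sace",
    "empirical_tau",
]


def generate_covariates(config: ScenarioConfig, rng: np.random.Generator):
    """Draw baseline covariates: binary sex V1, genotype U, residence D, and
    mean-centred uniform age V2."""
    cov = config.covariates
    cov.validate()
    n = config.n_participants
    V1 = (rng.random(n) < cov.p_sex).astype(np.int8)
    U = (rng.random(n) < cov.p_genotype).astype(np.int8)
    D = (rng.random(n) < cov.p_residence).astype(np.int8)
    V2 = rng.uniform(-cov.age_range, cov.age_range, size=n)
    return V1, V2, U, D


def generate_exposure(V1, V2, coefs, rng: np.random.Generator) -> np.ndarray:
    """Exposure depends on sex and age only (never on U or D)."""
    p = expit(coefs.intercept + coefs.sex * np.asarray(V1) + coefs.age * np.asarray(V2))
    return (rng.random(len(p)) < p).astype(np.int8)


def _survival_probs(V1, V2, U, coefs, alpha_UZ, center_u=True, p_u=0.5):
    u_eff = np.asarray(U, float) - (p_u if center_u else 0.0)
    base = coefs.intercept + coefs.sex * np.asarray(V1) + coefs.age * np.asarray(V2) \
        + alpha_UZ * u_eff
    return expit(base), expit(base + coefs.exposure)  # (p0, p1)


def generate_potential_survival(V1, V2, U, coefs, alpha_UZ, monotonicity,
                                rng: np.random.Generator, *,
                                coupling: str = "conditional",
                                center_confounder: bool = True,
                                p_genotype: float = 0.5):
    """Draw the joint potential survival pair (Z(0), Z(1)).

    Under valid monotonicity, Z(0) is generated only among those with
    Z(1)=1, so Z(0) <= Z(1) by construction and there are no
    defiant-survivors.  Two couplings are offered for the conditional law
    of Z(0) there: ``"conditional"`` (default) draws Bernoulli(p0), the
    survival model evaluated at a=0 within the surviving-under-exposure
    subset; ``"marginal"`` draws Bernoulli(p0/p1), the unique monotone
    coupling that preserves the a=0 marginal P(Z(0)=1) = p0 (possible
    because the non-negative exposure effect guarantees p0 <= p1).  When
    the monotonicity assumption is violated by design, Z(0) ~ Bernoulli(p0)
    for everyone, independently of Z(1), so defiant-survivors (Z0=1, Z1=0)
    occur.

    With ``center_confounder`` the unmeasured confounder enters the linear
    predictor centred at its mean, keeping marginal mortality comparable
    across scenarios that differ only in alpha_UZ.
    """
    p0, p1 = _survival_probs(V1, V2, U, coefs, alpha_UZ,
                             center_u=center_confounder, p_u=p_genotype)
    n = len(p0)
    Z1 = (rng.random(n) < p1).astype(np.int8)
    if monotonicity == MONOTONICITY_VALID:
        if np.any(p0 > p1 * (1 + 1e-12)):
            raise ConfigurationError(
                "monotone design violated: some participants have "
                "P(Z(0)=1) > P(Z(1)=1); the exposure coefficient must be >= 0"
            )
        if coupling == "marginal":
            cond = np.minimum(1.0, p0 / p1)
        elif coupling == "conditional":
            cond = p0
        else:
            raise ConfigurationError(f"unknown monotone coupling {coupling!r}")
        Z0 = np.where(Z1 == 1, (rng.random(n) < cond).astype(np.int8), 0).astype(np.int8)
    else:
        Z0 = (rng.random(n) < p0).astype(np.int8)
    return Z0, Z1


def _outcome_base(V1, V2, U, coefs, beta_UY):
    return coefs.intercept + coefs.sex * np.asarray(V1) + coefs.age * np.asarray(V2) \
        + beta_UY * np.asarray(U)


def generate_potential_outcomes(V1, V2, U, Z0, Z1, coefs, beta_UY, beta_A,
                                rng: np.random.Generator):
    """Draw Y(0) and Y(1), each defined only where the matching Z(a)=1.

    A single uniform per participant thresholds both potential outcomes
    (common random numbers), which leaves the marginal laws untouched while
    making the pair comparable within participant.
    """
    base = _outcome_base(V1, V2, U, coefs, beta_UY)
    u = rng.random(len(base))
    Y0 = np.where(np.asarray(Z0) == 1, (u < expit(base)).astype(float), np.nan)
    Y1 = np.where(np.asarray(Z1) == 1, (u < expit(base + beta_A)).astype(float), np.nan)
    return Y0, Y1


def generate_attendance(V1, V2, D, A, Z, coefs, rng: np.random.Generator) -> np.ndarray:
    """Attendance at follow-up among survivors; NaN (undefined) where Z=0."""
    lp = coefs.intercept + coefs.exposure * np.asarray(A) + coefs.sex * np.asarray(V1) \
        + coefs.age * np.asarray(V2) + coefs.residence * np.asarray(D)
    draws = (rng.random(len(lp)) < expit(lp)).astype(float)
    return np.where(np.asarray(Z) == 1, draws, np.nan)


def assemble_observed(V1, V2, U, D, A, Z0, Z1, Y0, Y1, R) -> PotentialCohort:
    """Resolve realized survival/outcome from the potential tables.

    Z = Z(A); the observed outcome is Y(A) for surviving attenders, missing
    (NaN with R=0) for surviving non-attenders, undefined (NaN with Z=0)
    for the deceased.
    """
    A = np.asarray(A)
    Z = np.where(A == 1, Z1, Z0).astype(np.int8)
    Y_of_A = np.where(A == 1, Y1, Y0)
    Y = np.where((Z == 1) & (R == 1), Y_of_A, np.nan)
    return PotentialCohort(
        V1=np.asarray(V1), V2=np.asarray(V2), U=np.asarray(U), D=np.asarray(D),
        A=A.astype(np.int8), Z0=np.asarray(Z0), Z1=np.asarray(Z1),
        stratum=assign_strata(Z0, Z1), Y0=Y0, Y1=Y1, Z=Z, R=R, Y=Y,
    )


def simulate_cohort(config: ScenarioConfig, beta_A: float,
                    rng: np.random.Generator) -> PotentialCohort:
    """Generate one full cohort (truth table) for a scenario."""
    V1, V2, U, D = generate_covariates(config, rng)
    A = generate_exposure(V1, V2, config.exposure, rng)
    Z0, Z1 = generate_potential_survival(
        V1, V2, U, config.survival, config.alpha_UZ, config.monotonicity, rng,
        coupling=config.monotone_coupling,
        center_confounder=config.center_survival_confounder,
        p_genotype=config.covariates.p_genotype,
    )
    Y0, Y1 = generate_potential_outcomes(
        V1, V2, U, Z0, Z1, config.outcome, config.beta_UY, beta_A, rng
    )
    Z = np.where(A == 1, Z1, Z0)
    R = generate_attendance(V1, V2, D, A, Z, config.attendance, rng)
    return assemble_observed(V1, V2, U, D, A, Z0, Z1, Y0, Y1, R)


# ---------------------------------------------------------------------------
# Truth-side summaries


def _log_odds_ratio(k1, n1, k0, n0):
    cells = (k1, n1 - k1, k0, n0 - k0)
    if min(cells) <= 0:
        raise DegenerateDataError(
            f"zero cell in 2x2 odds-ratio table {cells}; cohort too small or "
            "outcome prevalence too extreme"
        )
    return math.log((k1 / (n1 - k1)) / (k0 / (n0 - k0)))


def empirical_sace(cohort: PotentialCohort) -> float:
    """Empirical SACE log odds ratio from the truth table.

    ln of odds[Y(1)=1 | always-survivor] over odds[Y(0)=1 | always-survivor];
    both potential outcomes are defined for every always-survivor.
    """
    m = cohort.stratum == AS
    y1 = cohort.Y1[m]
    y0 = cohort.Y0[m]
    return _log_odds_ratio(int(np.nansum(y1)), int(m.sum()),
                           int(np.nansum(y0)), int(m.sum()))


def empirical_tau(cohort: PotentialCohort) -> float:
    """Empirical sensitivity parameter tau: odds of Y(1) among
    compliant-survivors over odds of Y(1) among always-survivors.

    Returns NaN (an undefined-tau signal, not an error) when the
    compliant-survivor stratum is empty or a cell count is zero.
    """
    mas = cohort.stratum == AS
    mcs = cohort.stratum == CS
    if mcs.sum() == 0:
        return float("nan")
    try:
        return math.exp(_log_odds_ratio(
            int(np.nansum(cohort.Y1[mcs])), int(mcs.sum()),
            int(np.nansum(cohort.Y1[mas])), int(mas.sum()),
        ))
    except DegenerateDataError:
        return float("nan")


# ---------------------------------------------------------------------------
# Calibration of the conditional exposure-outcome coefficient


def calibrate_exposure_coefficient(config: ScenarioConfig,
                                   target_sace_or: float | None = None,
                                   n_calib: int = 1_000_000,
                                   tol: float = 0.002,
                                   rng: np.random.Generator | None = None) -> float:
    """Find beta_A so the marginal always-survivor odds ratio equals the target.

    Because odds ratios are non-collapsible and the always-survivor stratum's
    covariate/U composition shifts with (alpha_UZ, beta_UY, monotonicity),
    the conditional coefficient that achieves a given *marginal* stratum-level
    odds ratio differs between scenarios, so calibration is per scenario.

    One calibration cohort of ``n_calib`` participants is drawn once
    (covariates, U and the potential-survival pair).  The objective then uses
    the conditional mean outcome probabilities averaged over the realized
    always-survivor stratum rather than re-thresholding binary draws — the
    same estimand with the binomial noise integrated out, which makes the
    response a smooth strictly increasing function of beta_A suitable for a
    root bracketer.  Root-finding uses Brent's method; the bracket is widened
    twice before giving up.
    """
    target = config.target_sace_or if target_sace_or is None else target_sace_or
    if not target > 0:
        raise CalibrationError(f"target odds ratio {target} must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, 999]))
    calib_cfg = config.with_(n_participants=int(n_calib))
    V1, V2, U, _ = generate_covariates(calib_cfg, rng)
    Z0, Z1 = generate_potential_survival(
        V1, V2, U, config.survival, config.alpha_UZ, config.monotonicity, rng,
        coupling=config.monotone_coupling,
        center_confounder=config.center_survival_confounder,
        p_genotype=config.covariates.p_genotype,
    )
    m = assign_strata(Z0, Z1) == AS
    if m.sum() < 100:
        raise CalibrationError(
            f"only {int(m.sum())} always-survivors in calibration cohort"
        )
    base = _outcome_base(V1[m], V2[m], U[m], config.outcome, config.beta_UY)
    pi0 = float(np.mean(expit(base)))
    log_odds0 = math.log(pi0 / (1 - pi0))
    log_target = math.log(target)

    def f(b):
        pi1 = float(np.mean(expit(base + b)))
        return math.log(pi1 / (1 - pi1)) - log_odds0 - log_target

    lo, hi = -4.0, 4.0
    for _ in range(3):
        if f(lo) * f(hi) <= 0:
            break
        lo, hi = lo * 2, hi * 2
    else:
        raise CalibrationError(
            f"could not bracket target OR {target} in beta_A in [{lo}, {hi}]: "
            f"f({lo})={f(lo):.4f}, f({hi})={f(hi):.4f}"
        )
    beta_A = brentq(f, lo, hi, xtol=1e-8)
    resid = abs(f(beta_A))
    if resid > tol:
        raise CalibrationError(f"calibration residual {resid:.3g} exceeds tol {tol}")
    return float(beta_A)
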