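"""Closed-form principal-stratification sensitivity analysis for the SACE.

The always-survivor stratum is not identifiable from observed data: survivors
under exposure mix always-survivors with compliant-survivors (those who
survive only if exposed).  The sensitivity parameter tau is the ratio of the
odds of the outcome under exposure among compliant-survivors to that among
always-survivors; tau = 1 encodes "no survival bias".  Given tau and four
model-based marginal quantities —

    nu_a : marginal probability of survival under exposure level a,
    xi_a : marginal probability of surviving AND having the outcome under a,

the SACE odds ratio has a closed form (a quadratic root for tau != 1, a
simple ratio in the tau -> 1 limit).  The marginal quantities come from
arm-specific outcome models fitted to attenders (assuming the outcome is
missing at random given measured covariates) whose predictions extend to all
survivors, and one survival model fitted to the full baseline cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import ObservedCohort
from .errors import DegenerateDataError, EstimationError
from .glm import fit_logistic
from .msm import _design, bc_bootstrap_ci
from .records import EstimateRecord

__all__ = [
    "MarginalQuantities",
    "fit_arm_outcome_models",
    "fit_marginal_survival",
    "marginal_quantities",
    "sace_or",
    "estimate_sensitivity",
    "sensitivity_curve",
]

_TAU_ONE_EPS = 1e-8
DEFAULT_TAU_GRID = (0.5, 1.0, 2.0)


@dataclass
class MarginalQuantities:
    """(nu_0, nu_1, xi_0, xi_1) with the invariant 0 < xi_a < nu_a <= 1."""

    nu0: float
    nu1: float
    xi0: float
    xi1: float

    def __post_init__(self):
        for a, nu, xi in ((0, self.nu0, self.xi0), (1, self.nu1, self.xi1)):
            if not (0 < xi < nu <= 1):
                raise EstimationError(
                    f"inconsistent marginal quantities at a={a}: "
                    f"xi={xi:.4g}, nu={nu:.4g} (need 0 < xi < nu <= 1)"
                )

    def as_tuple(self):
        return self.nu0, self.nu1, self.xi0, self.xi1


def fit_arm_outcome_models(obs: ObservedCohort):
    """Predict the outcome probability h_i(a) for every survivor, a in {0,1}.

    One logistic model of Y on the measured covariates is fitted per observed
    exposure arm, using attenders with an observed outcome (the only rows
    where Y exists; valid under missingness at random given covariates).
    Predictions are produced for *all* survivors — attenders and
    non-attenders alike — under both the observed and counterfactual
    exposure.  Attendance never enters the model.

    Returns (h0, h1): full-length arrays, NaN for non-survivors.
    """
    cc = obs.analysis_mask
    surv = obs.survivor_mask
    h = {}
    for a in (0, 1):
        arm = cc & (obs.A == a)
        if arm.sum() == 0:
            raise DegenerateDataError(f"no complete cases in arm A={a}")
        y = obs.Y[arm]
        if y.min() == y.max():
            raise DegenerateDataError(
                f"arm A={a} has no outcome variation among attenders")
        X, keep = _design([obs.V1[arm], obs.V2[arm]])
        fit = fit_logistic(y, X)
        Xs, _ = _design([obs.V1[surv], obs.V2[surv]], keep)
        out = np.full(obs.n, np.nan)
        out[surv] = fit.predict(Xs)
        h[a] = out
    return h[0], h[1]


def fit_marginal_survival(obs: ObservedCohort):
    """Predict the survival probability g_i(a) for every baseline participant.

    A single logistic model of Z on exposure and measured covariates is
    fitted to the full cohort; g_i(0) and g_i(1) are the fitted values with
    the exposure set to 0 and 1 in the linear predictor.
    """
    X, keep = _design([obs.A, obs.V1, obs.V2])
    fit = fit_logistic(obs.Z, X)
    X0, _ = _design([np.zeros(obs.n), obs.V1, obs.V2], keep)
    X1, _ = _design([np.ones(obs.n), obs.V1, obs.V2], keep)
    return fit.predict(X0), fit.predict(X1)


def marginal_quantities(g0, g1, h0, h1, Z, *,
                        nu_population: str = "all") -> MarginalQuantities:
    """Combine survival and outcome predictions into (nu, xi).

    xi_a averages g_i(a) * h_i(a) over survivors.  nu_a averages g_i(a) over
    the full baseline cohort by default (``nu_population="all"``; a marginal
    survival probability refers to the baseline population) or over
    survivors only (``"survivors"``, the strictly literal composite
    reading — see the methods note).
    """
    Z = np.asarray(Z)
    surv = Z == 1
    if surv.sum() == 0:
        raise DegenerateDataError("no survivors")
    if nu_population == "all":
        nu0, nu1 = float(np.mean(g0)), float(np.mean(g1))
    elif nu_population == "survivors":
        nu0, nu1 = float(np.mean(g0[surv])), float(np.mean(g1[surv]))
    else:
        raise ValueError(f"nu_population={nu_population!r}")
    xi0 = float(np.mean(np.asarray(g0)[surv] * np.asarray(h0)[surv]))
    xi1 = float(np.mean(np.asarray(g1)[surv] * np.asarray(h1)[surv]))
    return MarginalQuantities(nu0=nu0, nu1=nu1, xi0=xi0, xi1=xi1)


def sace_or(nu0, nu1, xi0, xi1, tau) -> float:
    """Closed-form SACE odds ratio at sensitivity parameter tau.

    For tau != 1 the always-survivor outcome probability under exposure is
    the root of a quadratic, giving

        SACE_OR = [(nu0+xi1)(tau-1) - tau*nu1 + q] /
                  [(nu0-xi1)(tau-1) + tau*nu1 - q] * (nu0-xi0)/xi0,
        q = sqrt{ [(nu0+xi1)(1-tau) + tau*nu1]^2 + 4*xi1*nu0*(tau-1) };

    at tau = 1 (within 1e-8) this reduces to

        SACE_OR = xi1*(nu0-xi0) / (xi0*(nu1-xi1)).
    """
    if not tau > 0:
        raise ValueError(f"tau={tau} must be positive")
    MarginalQuantities(nu0, nu1, xi0, xi1)  # validates the invariant region
    if abs(tau - 1.0) <= _TAU_ONE_EPS:
        return xi1 * (nu0 - xi0) / (xi0 * (nu1 - xi1))
    radicand = ((nu0 + xi1) * (1 - tau) + tau * nu1) ** 2 + 4 * xi1 * nu0 * (tau - 1)
    if radicand < 0:
        raise EstimationError(
            f"negative radicand in closed form: nu=({nu0:.4g},{nu1:.4g}), "
            f"xi=({xi0:.4g},{xi1:.4g}), tau={tau:.4g}")
    q = math.sqrt(radicand)
    num = (nu0 + xi1) * (tau - 1) - tau * nu1 + q
    den = (nu0 - xi1) * (tau - 1) + tau * nu1 - q
    # For tau < 1 both parts are negative; only the ratio must be positive
    # (it is the odds of the outcome among exposed always-survivors).
    if den == 0 or num / den <= 0:
        raise EstimationError(
            f"closed form outside its valid domain (num={num:.4g}, den={den:.4g}) "
            f"at nu=({nu0:.4g},{nu1:.4g}), xi=({xi0:.4g},{xi1:.4g}), tau={tau:.4g}")
    return num / den * (nu0 - xi0) / xi0


def _sens_point(obs: ObservedCohort, tau: float, nu_population: str) -> float:
    h0, h1 = fit_arm_outcome_models(obs)
    g0, g1 = fit_marginal_survival(obs)
    mq = marginal_quantities(g0, g1, h0, h1, obs.Z, nu_population=nu_population)
    return math.log(sace_or(*mq.as_tuple(), tau))


def estimate_sensitivity(obs: ObservedCohort, tau: float, *,
                         nu_population: str = "all",
                         bootstrap_B: int = 0, level: float = 0.95,
                         seed=None) -> EstimateRecord:
    """Sensitivity-analysis SACE estimate at a single tau, with optional
    bias-corrected bootstrap interval (resampling baseline participants and
    refitting every model per resample)."""
    h0, h1 = fit_arm_outcome_models(obs)
    g0, g1 = fit_marginal_survival(obs)
    mq = marginal_quantities(g0, g1, h0, h1, obs.Z, nu_population=nu_population)
    log_or = math.log(sace_or(*mq.as_tuple(), tau))
    rec = EstimateRecord(method=f"sens@{tau:g}", log_or=log_or,
                         n_used=int(obs.n_survivors),
                         extra={"nu0": mq.nu0, "nu1": mq.nu1,
                                "xi0": mq.xi0, "xi1": mq.xi1})
    if bootstrap_B:
        rng = np.random.default_rng(seed)
        lo, hi, n_failed = bc_bootstrap_ci(
            obs, lambda o: _sens_point(o, tau, nu_population), log_or,
            B=bootstrap_B, level=level, rng=rng)
        rec.ci_low, rec.ci_high = lo, hi
        rec.extra["bootstrap_failures"] = n_failed
    return rec


def sensitivity_curve(obs: ObservedCohort, tau_grid=DEFAULT_TAU_GRID, *,
                      nu_population: str = "all", bootstrap_B: int = 0,
                      level: float = 0.95, seed=None) -> dict:
    """Run the full pipeline over a grid of tau values.

    Models are fitted once and shared across the grid (only the closed form
    depends on tau).  A failure at one grid point is recorded as a
    non-converged record and does not abort the others.  Returns
    {tau: EstimateRecord}.
    """
    h0, h1 = fit_arm_outcome_models(obs)
    g0, g1 = fit_marginal_survival(obs)
    mq = marginal_quantities(g0, g1, h0, h1, obs.Z, nu_population=nu_population)
    out = {}
    ss = np.random.SeedSequence(seed)
    for tau, child in zip(tau_grid, ss.spawn(len(list(tau_grid)))):
        if not tau > 0:
            raise ValueError(f"tau={tau} must be positive")
        try:
            log_or = math.log(sace_or(*mq.as_tuple(), tau))
        except (EstimationError, ValueError) as exc:
            warnings.warn(f"sensitivity estimate failed at tau={tau}: {exc}",
                          RuntimeWarning)
            out[tau] = EstimateRecord(method=f"sens@{tau:g}", log_or=float("nan"),
                                      converged=False, extra={"error": str(exc)})
            continue
        rec = EstimateRecord(method=f"sens@{tau:g}", log_or=log_or,
                             n_used=int(obs.n_survivors),
                             extra={"nu0": mq.nu0, "nu1": mq.nu1,
                                    "xi0": mq.xi0, "xi1": mq.xi1})
        if bootstrap_B:
            rng = np.random.default_rng(child)
            try:
                lo, hi, n_failed = bc_bootstrap_ci(
                    obs, lambda o: _sens_point(o, tau, nu_population), log_or,
                    B=bootstrap_B, level=level, rng=rng)
                rec.ci_low, rec.ci_high = lo, hi
                rec.extra["bootstrap_failures"] = n_failed
            except EstimationError as exc:
                rec.extra["ci_error"] = str(exc)
        out[tau] = rec
    return out
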