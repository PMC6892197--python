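"""Marginal structural model for the SACE with stabilized inverse-probability weights.

The estimator fits three logistic propensity models on the observed cohort —
exposure given measured confounders (sex, age), survival given exposure and
measured confounders, and attendance among survivors given exposure and
measured confounders — and combines them into one stabilized weight per
surviving participant:

    W_i = SF_{A_i} / [ (A_i p_i + (1-A_i)(1-p_i)) * q_i * m_i ]

where p, q, m are the fitted exposure, survival and attendance propensities
and SF_a are per-exposure-group stabilizing constants.  A weighted logistic
regression of the observed outcome on exposure and baseline confounders over
surviving attenders then yields the exposure coefficient as the SACE log
odds ratio.  In the weighted pseudo-population, survivors stand in for
participants with similar covariates who died or did not attend; the
estimate is unbiased for the SACE when survival and attendance are correctly
modelled by measured covariates, i.e. when no unmeasured survival-outcome
confounder is present.

Intervals come from a bias-corrected nonparametric bootstrap that resamples
baseline participants and refits the entire pipeline per resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .cohort import ObservedCohort
from .errors import DegenerateDataError, EstimationError
from .glm import fit_logistic
from .records import EstimateRecord

__all__ = [
    "PropensityWeights",
    "fit_propensity",
    "stabilizing_factors",
    "compute_weights",
    "fit_msm",
    "estimate_msm",
    "standardized_difference",
    "balance_table",
    "bc_bootstrap_ci",
    "bc_interval",
]

_CLIP = 1e-12


def _design(cols, keep=None):
    """Intercept-plus-covariates design matrix.

    Constant covariate columns are dropped (they are collinear with the
    intercept); ``keep`` replays a previous selection so fitted models can
    predict on counterfactual inputs with an identical column layout.
    Returns ``(X, keep)``.
    """
    cols = [np.asarray(c, float) for c in cols]
    n = len(cols[0])
    if keep is None:
        keep = [i for i, c in enumerate(cols) if np.ptp(c) > 0]
    X = np.column_stack([np.ones(n)] + [cols[i] for i in keep])
    return X, keep


@dataclass
class PropensityWeights:
    """Fitted propensities and the stabilized weight they imply.

    ``p``, ``q`` are full-length; ``m`` and ``W`` are NaN (undefined) for
    participants who do not survive to follow-up.
    """

    p: np.ndarray
    q: np.ndarray
    m: np.ndarray
    SF0: float
    SF1: float
    W: np.ndarray

    @classmethod
    def from_cohort(cls, obs: "ObservedCohort", *, literal_eq6: bool = False,
                    cap_percentile: float | None = None) -> "PropensityWeights":
        p = fit_propensity(obs, "exposure")
        q = fit_propensity(obs, "survival")
        m = fit_propensity(obs, "attendance")
        SF0, SF1 = stabilizing_factors(p, obs.A, literal_eq6=literal_eq6)
        W = compute_weights(p, q, m, SF0, SF1, obs.A, obs.Z,
                            cap_percentile=cap_percentile)
        return cls(p=p, q=q, m=m, SF0=SF0, SF1=SF1, W=W)


def fit_propensity(obs: ObservedCohort, role: str) -> np.ndarray:
    """Fit one of the three propensity models and return fitted probabilities.

    role = "exposure":   P(A=1 | V1, V2) on all N.
    role = "survival":   P(Z=1 | A, V1, V2) on all N.
    role = "attendance": P(R=1 | A, V1, V2) on survivors; full-length vector
                         with NaN for non-survivors.

    U and D are unmeasured by construction and never enter.  Fitted values
    are defensively clipped away from {0, 1}, with a warning if the clip
    ever triggers.
    """
    if role == "exposure":
        X, _ = _design([obs.V1, obs.V2])
        fit = fit_logistic(obs.A, X)
        p = fit.fitted
    elif role == "survival":
        if obs.Z.min() == obs.Z.max():
            raise DegenerateDataError("no variation in survival status")
        X, _ = _design([obs.A, obs.V1, obs.V2])
        fit = fit_logistic(obs.Z, X)
        p = fit.fitted
    elif role == "attendance":
        m = obs.survivor_mask
        if m.sum() == 0:
            raise DegenerateDataError("no survivors to fit attendance on")
        X, _ = _design([obs.A[m], obs.V1[m], obs.V2[m]])
        fit = fit_logistic(obs.R[m], X)
        p = np.full(obs.n, np.nan)
        p[m] = fit.fitted
    else:
        raise ValueError(f"unknown propensity role {role!r}")
    finite = ~np.isnan(p)
    if np.any((p[finite] < _CLIP) | (p[finite] > 1 - _CLIP)):
        warnings.warn(f"{role} propensities clipped away from 0/1", RuntimeWarning)
        p = np.where(finite, np.clip(p, _CLIP, 1 - _CLIP), p)
    return p


def stabilizing_factors(p, A, *, literal_eq6: bool = False):
    """Per-exposure-group stabilizing constants (SF0, SF1).

    Default: the average probability of the *observed* exposure level within
    each group — SF1 = mean(p | A=1), SF0 = mean(1-p | A=0) — so the weight
    numerator is an estimate of P(A = A_i), the standard stabilized-weight
    construction.  ``literal_eq6=True`` instead averages p itself in both
    groups (a transcription-faithful variant).
    """
    p = np.asarray(p, float)
    A = np.asarray(A)
    if (A == 1).sum() == 0 or (A == 0).sum() == 0:
        raise DegenerateDataError("an exposure group is empty")
    SF1 = float(np.mean(p[A == 1]))
    SF0 = float(np.mean(p[A == 0])) if literal_eq6 else float(np.mean(1 - p[A == 0]))
    return SF0, SF1


def compute_weights(p, q, m, SF0, SF1, A, Z, *, cap_percentile: float | None = None):
    """Final stabilized weight per participant; NaN (undefined) where Z=0.

    Weights are never truncated by default; if ``cap_percentile`` is given,
    weights above that percentile (among survivors) are capped and a warning
    is emitted.
    """
    p, q, m_arr, A, Z = (np.asarray(x, float) for x in (p, q, m, A, Z))
    surv = Z == 1
    for name, comp in (("p", p[surv]), ("q", q[surv]), ("m", m_arr[surv])):
        if np.any(comp <= 0):
            raise EstimationError(f"non-positive {name} propensity among survivors")
    sf = np.where(A == 1, SF1, SF0)
    denom = (A * p + (1 - A) * (1 - p)) * q * m_arr
    W = np.where(surv, sf / denom, np.nan)
    if cap_percentile is not None:
        cap = np.nanpercentile(W, cap_percentile)
        n_over = int(np.nansum(W > cap))
        if n_over:
            warnings.warn(
                f"capping {n_over} weight(s) above the {cap_percentile}th "
                f"percentile ({cap:.3g})", RuntimeWarning)
            W = np.where(W > cap, cap, W)
    return W


def fit_msm(obs: ObservedCohort, W) -> EstimateRecord:
    """Weighted logistic regression of the outcome on exposure and baseline
    confounders over complete-case surviving attenders; the exposure
    coefficient is the SACE log odds ratio."""
    mask = obs.analysis_mask
    if mask.sum() == 0:
        raise DegenerateDataError("no complete-case surviving attenders")
    W = np.asarray(W, float)
    X, keep = _design([obs.A[mask], obs.V1[mask], obs.V2[mask]])
    if 0 not in keep:
        raise DegenerateDataError("exposure is constant among analysed rows")
    a_col = 1 + keep.index(0)
    try:
        fit = fit_logistic(obs.Y[mask], X, weights=W[mask])
    except EstimationError as exc:
        return EstimateRecord(method="msm", log_or=float("nan"), converged=False,
                              n_used=int(mask.sum()), extra={"error": str(exc)})
    # Sandwich (robust) SE for the exposure coefficient — diagnostic only;
    # the canonical interval is the bias-corrected bootstrap, which also
    # absorbs the variability of the estimated weights.
    w = W[mask]
    mu = fit.fitted
    bread = np.linalg.inv((X * (w * mu * (1 - mu))[:, None]).T @ X)
    score_rows = X * (w * (obs.Y[mask] - mu))[:, None]
    cov = bread @ (score_rows.T @ score_rows) @ bread
    return EstimateRecord(method="msm", log_or=float(fit.coef[a_col]),
                          converged=fit.converged, n_used=int(mask.sum()),
                          extra={"robust_se": float(np.sqrt(cov[a_col, a_col]))})


def _msm_point(obs: ObservedCohort) -> EstimateRecord:
    pw = PropensityWeights.from_cohort(obs)
    rec = fit_msm(obs, pw.W)
    rec.extra["weights"] = pw.W
    return rec


def estimate_msm(obs: ObservedCohort, *, bootstrap_B: int = 0, level: float = 0.95,
                 seed=None) -> EstimateRecord:
    """Full MSM pipeline: propensities, weights, weighted fit, optional
    bias-corrected bootstrap interval, and a pre/post balance table."""
    rec = _msm_point(obs)
    W = rec.extra.pop("weights")
    mask = obs.analysis_mask
    rec.extra["weight_summary"] = {
        "min": float(np.nanmin(W[mask])), "median": float(np.nanmedian(W[mask])),
        "max": float(np.nanmax(W[mask])),
    }
    rec.extra["balance"] = balance_table(obs, W)
    if bootstrap_B and rec.converged:
        rng = np.random.default_rng(seed)
        lo, hi, n_failed = bc_bootstrap_ci(
            obs, lambda o: _msm_point(o).log_or, rec.log_or,
            B=bootstrap_B, level=level, rng=rng)
        rec.ci_low, rec.ci_high = lo, hi
        rec.extra["bootstrap_failures"] = n_failed
        if n_failed > 0.1 * bootstrap_B:
            rec.extra["ci_unreliable"] = True
            warnings.warn(f"{n_failed}/{bootstrap_B} bootstrap resamples failed; "
                          "interval unreliable", RuntimeWarning)
    return rec


# ---------------------------------------------------------------------------
# Balance diagnostics


def standardized_difference(x, group, weights=None) -> float:
    """Standardized difference of a covariate between two exposure groups.

    Group means (proportions for binary variables) differ by the pooled
    standard deviation sqrt((s0^2 + s1^2)/2); for binary x this reduces to
    the familiar (p0 - p1) / sqrt((p0(1-p0) + p1(1-p1))/2).  Weighted calls
    substitute weighted means and variances.  Sign convention: unexposed
    minus exposed.  Raises on zero pooled variance.
    """
    x = np.asarray(x, float)
    group = np.asarray(group)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    stats = {}
    for g in (0, 1):
        m = group == g
        if m.sum() == 0:
            raise DegenerateDataError(f"group {g} is empty")
        mean = np.average(x[m], weights=w[m])
        var = np.average((x[m] - mean) ** 2, weights=w[m])
        stats[g] = (mean, var)
    pooled = np.sqrt((stats[0][1] + stats[1][1]) / 2.0)
    if pooled == 0:
        raise DegenerateDataError("zero pooled variance; standardized difference undefined")
    return float((stats[0][0] - stats[1][0]) / pooled)


def balance_table(obs: ObservedCohort, W) -> dict:
    """Standardized differences for V1 and V2 between exposure groups among
    analysed rows, before and after weighting."""
    mask = obs.analysis_mask
    W = np.asarray(W, float)
    out = {}
    for name, col in (("V1", obs.V1), ("V2", obs.V2)):
        col = np.asarray(col, float)[mask]
        grp = obs.A[mask]
        out[name] = {
            "unweighted": standardized_difference(col, grp),
            "weighted": standardized_difference(col, grp, weights=W[mask]),
        }
    return out


# ---------------------------------------------------------------------------
# Bias-corrected bootstrap


def bc_bootstrap_ci(obs: ObservedCohort, estimator, theta_hat: float, *,
                    B: int = 1000, level: float = 0.95, rng=None):
    """Bias-corrected percentile bootstrap interval.

    Resamples baseline participants with replacement and re-runs
    ``estimator`` (the full pipeline) per resample.  The bias-correction
    constant is z0 = Phi^-1(F), where F is the fraction of bootstrap
    estimates below the point estimate (ties counted half each, avoiding
    Phi^-1 pathologies at small B); interval endpoints are the bootstrap
    quantiles at Phi(2 z0 +/- z_alpha).  Failed resamples are dropped and
    counted.  Returns (lo, hi, n_failed).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    thetas = []
    n_failed = 0
    for _ in range(B):
        boot = obs.resample(rng)
        try:
            t = estimator(boot)
        except (EstimationError, DegenerateDataError):
            n_failed += 1
            continue
        if not np.isfinite(t):
            n_failed += 1
            continue
        thetas.append(t)
    thetas = np.asarray(thetas)
    if thetas.size < 2:
        raise EstimationError(f"only {thetas.size} successful bootstrap resamples")
    lo, hi = bc_interval(thetas, theta_hat, level=level)
    return lo, hi, n_failed


def bc_interval(thetas, theta_hat: float, *, level: float = 0.95):
    """Bias-corrected interval endpoints from bootstrap estimates.

    z0 = Phi^-1 of the fraction of estimates below the point estimate (ties
    count half); endpoints are the empirical quantiles at Phi(2 z0 +/-
    z_alpha).  With z0 = 0 — a bootstrap distribution whose median is the
    point estimate — this reduces exactly to the percentile interval.
    """
    thetas = np.asarray(thetas, float)
    if np.ptp(thetas) == 0:
        warnings.warn("degenerate bootstrap distribution; zero-width interval",
                      RuntimeWarning)
        return float(thetas[0]), float(thetas[0])
    frac = (np.sum(thetas < theta_hat) + 0.5 * np.sum(thetas == theta_hat)) / thetas.size
    frac = min(max(frac, 0.5 / thetas.size), 1 - 0.5 / thetas.size)
    z0 = norm.ppf(frac)
    za = norm.ppf(0.5 + level / 2.0)
    lo_q = norm.cdf(2 * z0 - za)
    hi_q = norm.cdf(2 * z0 + za)
    lo, hi = np.quantile(thetas, [lo_q, hi_q])
    return float(lo), float(hi)
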