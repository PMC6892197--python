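"""MSM estimator: propensities, stabilized weights, balance, bootstrap."""

import numpy as np
import pytest

from sacekit.cohort import ObservedCohort
from sacekit.errors import DegenerateDataError, EstimationError
from sacekit.glm import fit_logistic
from sacekit.msm import (balance_table, bc_interval, compute_weights,
                         estimate_msm, fit_msm, fit_propensity,
                         stabilizing_factors, standardized_difference,
                         PropensityWeights)
from sacekit.simulate import simulate_cohort


def _obs(A, Y, V1=None, V2=None, Z=None, R=None):
    n = len(A)
    z = np.ones(n, dtype=np.int8) if Z is None else np.asarray(Z, np.int8)
    r = np.ones(n, float) if R is None else np.asarray(R, float)
    return ObservedCohort(
        V1=np.zeros(n, np.int8) if V1 is None else np.asarray(V1, np.int8),
        V2=np.zeros(n) if V2 is None else np.asarray(V2, float),
        A=np.asarray(A, np.int8), Z=z,
        R=np.where(z == 1, r, np.nan),
        Y=np.where((z == 1) & (r == 1), np.asarray(Y, float), np.nan))


class TestPropensity:
    def test_constant_covariates_reduce_to_prevalence(self):
        obs = _obs(A=[1, 1, 1, 0, 0, 0, 0, 0, 0, 0], Y=[0] * 10)
        p = fit_propensity(obs, "exposure")
        np.testing.assert_allclose(p, 0.3, atol=1e-8)

    def test_mean_propensity_equals_prevalence(self, observed_cohort):
        """The logistic score equation with an intercept forces the fitted
        probabilities to average to the observed prevalence."""
        p = fit_propensity(observed_cohort, "exposure")
        assert p.mean() == pytest.approx(observed_cohort.A.mean(), abs=1e-9)

    def test_attendance_undefined_for_nonsurvivors(self, observed_cohort):
        m = fit_propensity(observed_cohort, "attendance")
        assert np.isnan(m[observed_cohort.Z == 0]).all()
        assert np.isfinite(m[observed_cohort.Z == 1]).all()

    def test_degenerate_survival_raises(self):
        obs = _obs(A=[1, 0, 1, 0], Y=[0, 0, 1, 1])
        with pytest.raises(DegenerateDataError):
            fit_propensity(obs, "survival")


class TestStabilizingFactors:
    def test_hand_example(self):
        SF0, SF1 = stabilizing_factors(np.array([0.8, 0.6, 0.4]),
                                       np.array([1, 1, 0]))
        assert SF1 == pytest.approx(0.7)
        assert SF0 == pytest.approx(0.6)

    def test_literal_variant(self):
        SF0, SF1 = stabilizing_factors(np.array([0.8, 0.6, 0.4]),
                                       np.array([1, 1, 0]), literal_eq6=True)
        assert SF0 == pytest.approx(0.4)

    def test_constant_covariates_give_group_shares(self):
        p = np.full(10, 0.3)
        A = np.array([1] * 3 + [0] * 7)
        SF0, SF1 = stabilizing_factors(p, A)
        assert SF1 == pytest.approx(0.3)
        assert SF0 == pytest.approx(0.7)

    def test_empty_group_raises(self):
        with pytest.raises(DegenerateDataError):
            stabilizing_factors(np.array([0.5]), np.array([1]))


class TestWeights:
    def test_hand_example(self):
        W = compute_weights(p=[0.5], q=[0.5], m=[0.5], SF0=0.5, SF1=0.5,
                            A=[1], Z=[1])
        assert W[0] == pytest.approx(4.0)

    def test_undefined_for_nonsurvivors_and_positive_otherwise(self, observed_cohort):
        pw = PropensityWeights.from_cohort(observed_cohort)
        dead = observed_cohort.Z == 0
        assert np.isnan(pw.W[dead]).all()
        assert (pw.W[~dead] > 0).all()

    def test_nonpositive_propensity_rejected(self):
        with pytest.raises(EstimationError):
            compute_weights(p=[0.5], q=[0.0], m=[0.5], SF0=0.5, SF1=0.5,
                            A=[1], Z=[1])

    def test_capping_warns(self):
        p = np.array([0.5, 0.5, 0.01])
        with pytest.warns(RuntimeWarning):
            W = compute_weights(p=p, q=[0.5] * 3, m=[0.5] * 3, SF0=0.5, SF1=0.5,
                                A=[1, 1, 1], Z=[1, 1, 1], cap_percentile=50)
        assert W.max() <= np.median([4.0, 4.0, 200.0]) + 1e-9


class TestFitMsm:
    def test_unit_weights_coincide_with_plain_logistic(self, observed_cohort):
        mask = observed_cohort.analysis_mask
        rec = fit_msm(observed_cohort, np.ones(observed_cohort.n))
        X = np.column_stack([np.ones(mask.sum()), observed_cohort.A[mask],
                             observed_cohort.V1[mask], observed_cohort.V2[mask]])
        plain = fit_logistic(observed_cohort.Y[mask], X)
        assert rec.log_or == pytest.approx(plain.coef[1], abs=1e-9)

    def test_weighted_fit_matches_direct_maximization(self, observed_cohort):
        """The full weighted fit agrees with statsmodels on the same rows
        and weights (dual-route check of the headline estimate)."""
        sm = pytest.importorskip("statsmodels.api")
        pw = PropensityWeights.from_cohort(observed_cohort)
        rec = fit_msm(observed_cohort, pw.W)
        mask = observed_cohort.analysis_mask
        X = np.column_stack([np.ones(mask.sum()), observed_cohort.A[mask],
                             observed_cohort.V1[mask], observed_cohort.V2[mask]])
        ref = sm.GLM(observed_cohort.Y[mask], X, family=sm.families.Binomial(),
                     freq_weights=pw.W[mask]).fit()
        assert rec.log_or == pytest.approx(ref.params[1], abs=1e-6)


class TestStandardizedDifference:
    def test_identical_groups_give_zero(self):
        x = np.r_[np.ones(5), np.zeros(5), np.ones(5), np.zeros(5)]
        g = np.r_[np.zeros(10), np.ones(10)]
        assert standardized_difference(x, g) == 0.0

    @pytest.mark.parametrize("p_low,p_high,expected", [
        (0.912, 0.806, 0.31),   # country of birth, northern European descent
        (0.634, 0.571, 0.13),   # never-smokers
    ])
    def test_published_worked_examples(self, p_low, p_high, expected):
        """Binary standardized differences reproduce the printed cohort-table
        values at two decimal places."""
        n = 1000
        x = np.r_[np.ones(int(p_low * n)), np.zeros(n - int(p_low * n)),
                  np.ones(int(p_high * n)), np.zeros(n - int(p_high * n))]
        g = np.r_[np.zeros(n), np.ones(n)]
        assert round(standardized_difference(x, g), 2) == expected

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            standardized_difference(np.ones(6), np.r_[np.zeros(3), np.ones(3)])


class TestBalance:
    def test_weighting_improves_balance_in_most_replicates(self, calibrated_default):
        """Weighted standardized differences for sex and age shrink relative
        to unweighted among analysed rows in >= 95% of replicates."""
        cfg, beta_A = calibrated_default
        improved = 0
        n_reps = 30
        for rep in range(n_reps):
            cohort = simulate_cohort(cfg.with_(n_participants=4000), beta_A,
                                     np.random.default_rng([21, rep]))
            obs = cohort.observed()
            pw = PropensityWeights.from_cohort(obs)
            tab = balance_table(obs, pw.W)
            if all(abs(tab[v]["weighted"]) < abs(tab[v]["unweighted"])
                   for v in ("V1", "V2")):
                improved += 1
        assert improved >= int(0.95 * n_reps) - 1

    def test_unweighted_imbalance_is_substantial(self, observed_cohort):
        """Exposure depends on sex and age, so the pre-weighting standardized
        differences among analysed rows are far from zero."""
        tab = balance_table(observed_cohort, np.ones(observed_cohort.n))
        assert abs(tab["V1"]["unweighted"]) > 0.1
        assert abs(tab["V2"]["unweighted"]) > 0.1


class TestBcInterval:
    def test_symmetric_distribution_reduces_to_percentile(self):
        rng = np.random.default_rng(0)
        thetas = rng.normal(size=2001)
        thetas = np.sort(thetas)
        theta_hat = np.median(thetas)  # z0 = 0 by construction
        lo, hi = bc_interval(thetas, theta_hat)
        plo, phi = np.quantile(thetas, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-10)
        assert hi == pytest.approx(phi, abs=1e-10)

    def test_degenerate_distribution_zero_width_flagged(self):
        with pytest.warns(RuntimeWarning):
            lo, hi = bc_interval(np.full(100, 1.5), 1.5)
        assert lo == hi == 1.5

    def test_estimate_msm_interval_brackets_estimate(self, observed_cohort):
        rec = estimate_msm(observed_cohort, bootstrap_B=60, seed=5)
        assert rec.ci_low <= rec.log_or <= rec.ci_high
        assert rec.extra["bootstrap_failures"] == 0
        # diagnostic sandwich SE on the same scale as the bootstrap spread
        implied = (rec.ci_high - rec.ci_low) / (2 * 1.96)
        assert 0.5 * implied < rec.extra["robust_se"] < 2 * implied
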