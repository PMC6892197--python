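"""Cohort simulator: marginal laws, strata logic, undefinedness, calibration."""

import math

import numpy as np
import pytest

from sacekit.cohort import AS, CS, DS, NS, assign_strata
from sacekit.config import (ExposureCoefs, OutcomeCoefs, ScenarioConfig,
                            SurvivalCoefs)
from sacekit.errors import CalibrationError, ConfigurationError
from sacekit.simulate import (calibrate_exposure_coefficient, empirical_sace,
                              empirical_tau, generate_covariates,
                              generate_exposure, generate_potential_outcomes,
                              generate_potential_survival, generate_attendance,
                              simulate_cohort)


def _cfg(**kw):
    return ScenarioConfig(**kw)


class TestCovariates:
    def test_marginal_moments(self):
        cfg = _cfg(n_participants=200_000)
        V1, V2, U, D = generate_covariates(cfg, np.random.default_rng(0))
        for col in (V1, U, D):
            assert abs(col.mean() - 0.5) < 0.005
        assert abs(V2.mean()) < 0.05
        assert abs(V2.var() - 100 / 3) < 0.5

    def test_deterministic_under_seeding(self):
        cfg = _cfg(n_participants=5)
        a = generate_covariates(cfg, np.random.default_rng(99))
        b = generate_covariates(cfg, np.random.default_rng(99))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_invalid_probability_rejected(self):
        from sacekit.config import CovariateDist
        with pytest.raises(ConfigurationError):
            _cfg(covariates=CovariateDist(p_sex=1.5))
        with pytest.raises(ConfigurationError):
            _cfg(covariates=CovariateDist(age_range=-1.0))


class TestExposure:
    def test_null_coefficients_give_half(self):
        n = 200_000
        rng = np.random.default_rng(1)
        A = generate_exposure(np.zeros(n), np.zeros(n),
                              ExposureCoefs(0.0, 0.0, 0.0), rng)
        assert abs(A.mean() - 0.5) < 0.005

    def test_log2_intercept_matches_expit(self):
        # expit(ln 2) = 2/3 for a participant with V1 = V2 = 0.
        n = 300_000
        A = generate_exposure(np.zeros(n), np.zeros(n),
                              ExposureCoefs(math.log(2), 0.0, 0.0),
                              np.random.default_rng(2))
        assert abs(A.mean() - 2 / 3) < 0.005

    def test_default_marginal_prevalence_matches_integration_oracle(self):
        """Empirical exposure prevalence matches expit averaged over the
        covariate law by numeric integration."""
        from scipy.special import expit
        cfg = _cfg(n_participants=400_000)
        V1, V2, U, D = generate_covariates(cfg, np.random.default_rng(3))
        A = generate_exposure(V1, V2, cfg.exposure, np.random.default_rng(4))
        ages = np.linspace(-10, 10, 4001)
        marg = np.mean([expit(cfg.exposure.intercept + cfg.exposure.sex * v1
                              + cfg.exposure.age * ages).mean() for v1 in (0, 1)])
        assert abs(A.mean() - marg) < 0.004


class TestPotentialSurvival:
    def _homog(self, n, p0, p1, coupling, monotonicity="valid", seed=5):
        from scipy.special import logit
        coefs = SurvivalCoefs(intercept=logit(p0), exposure=logit(p1) - logit(p0),
                              sex=0.0, age=0.0)
        return generate_potential_survival(
            np.zeros(n), np.zeros(n), np.zeros(n), coefs, 0.0, monotonicity,
            np.random.default_rng(seed), coupling=coupling)

    def test_marginal_coupling_preserves_a0_law(self):
        Z0, Z1 = self._homog(300_000, 0.81, 0.9, "marginal")
        assert abs(Z1.mean() - 0.9) < 0.003
        assert abs(Z0.mean() - 0.81) < 0.003
        assert abs(Z0[Z1 == 1].mean() - 0.9) < 0.003

    def test_conditional_coupling_conditional_law(self):
        Z0, Z1 = self._homog(300_000, 0.81, 0.9, "conditional")
        assert abs(Z0[Z1 == 1].mean() - 0.81) < 0.003

    def test_no_defiant_survivors_under_valid_monotonicity(self):
        for coupling in ("conditional", "marginal"):
            Z0, Z1 = self._homog(50_000, 0.7, 0.9, coupling)
            assert np.sum((Z0 == 1) & (Z1 == 0)) == 0

    def test_violated_null_exposure_gives_equal_marginals(self):
        Z0, Z1 = self._homog(300_000, 0.8, 0.8, "conditional",
                             monotonicity="violated")
        assert abs(Z0.mean() - Z1.mean()) < 0.004

    def test_harmful_exposure_with_valid_monotonicity_rejected(self):
        with pytest.raises(ConfigurationError):
            self._homog(100, 0.9, 0.8, "conditional")


class TestStrata:
    @pytest.mark.parametrize("z0,z1,expected", [
        (1, 1, AS), (0, 1, CS), (1, 0, DS), (0, 0, NS)])
    def test_mapping(self, z0, z1, expected):
        assert assign_strata([z0], [z1])[0] == expected

    def test_partition(self, truth_cohort):
        counts = truth_cohort.stratum_counts()
        assert sum(counts.values()) == truth_cohort.n

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            assign_strata([2], [1])

    def test_violated_scenarios_contain_defiant_survivors(self, calibrated_default):
        cfg, beta_A = calibrated_default
        cohort = simulate_cohort(cfg.with_(monotonicity="violated"), beta_A,
                                 np.random.default_rng(8))
        assert cohort.stratum_counts()["DS"] > 0


class TestPotentialOutcomes:
    def test_undefined_exactly_where_dead(self, truth_cohort):
        assert np.array_equal(np.isnan(truth_cohort.Y0), truth_cohort.Z0 == 0)
        assert np.array_equal(np.isnan(truth_cohort.Y1), truth_cohort.Z1 == 0)

    def test_unit_confounder_odds_ratio_matches_design(self):
        """With beta_UY = ln 2 and identical other covariates the conditional
        odds ratio of Y(a) between U=1 and U=0 is 2."""
        n = 400_000
        U = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        Y0, _ = generate_potential_outcomes(
            np.zeros(n), np.zeros(n), U, np.ones(n), np.ones(n),
            OutcomeCoefs(intercept=-2.0, sex=0.0, age=0.0), math.log(2), 0.0,
            np.random.default_rng(6))
        odds = lambda p: p / (1 - p)
        ratio = odds(Y0[U == 1].mean()) / odds(Y0[U == 0].mean())
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_null_intercept_gives_half_prevalence(self):
        n = 100_000
        Y0, Y1 = generate_potential_outcomes(
            np.zeros(n), np.zeros(n), np.zeros(n), np.ones(n), np.ones(n),
            OutcomeCoefs(0.0, 0.0, 0.0), 0.0, 0.0, np.random.default_rng(7))
        assert abs(np.mean(Y0) - 0.5) < 0.006
        np.testing.assert_array_equal(Y0, Y1)  # common draw, identical laws


class TestAttendance:
    def test_undefined_for_the_dead(self, truth_cohort):
        assert np.array_equal(np.isnan(truth_cohort.R), truth_cohort.Z == 0)

    def test_null_coefficients_give_half(self):
        from sacekit.config import AttendanceCoefs
        n = 100_000
        R = generate_attendance(np.zeros(n), np.zeros(n), np.zeros(n),
                                np.zeros(n), np.ones(n),
                                AttendanceCoefs(0, 0, 0, 0, 0),
                                np.random.default_rng(9))
        assert abs(np.nanmean(R) - 0.5) < 0.006

    def test_residence_odds_ratio_matches_design(self):
        from sacekit.config import AttendanceCoefs
        n = 400_000
        D = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        R = generate_attendance(np.zeros(n), np.zeros(n), D, np.zeros(n),
                                np.ones(n),
                                AttendanceCoefs(0.5, 0, 0, 0, math.log(0.5)),
                                np.random.default_rng(10))
        odds = lambda p: p / (1 - p)
        ratio = odds(np.nanmean(R[D == 1])) / odds(np.nanmean(R[D == 0]))
        assert ratio == pytest.approx(0.5, rel=0.05)


class TestAssembleObserved:
    def test_observed_outcome_identities(self, truth_cohort):
        c = truth_cohort
        att = (c.Z == 1) & (c.R == 1)
        y_of_a = np.where(c.A == 1, c.Y1, c.Y0)
        np.testing.assert_array_equal(c.Y[att], y_of_a[att])
        assert np.isnan(c.Y[~att]).all()

    def test_missing_count_identity(self, truth_cohort):
        c = truth_cohort
        n_missing = np.sum((c.Z == 1) & np.isnan(c.Y))
        assert n_missing == np.sum((c.Z == 1) & (c.R == 0))

    def test_observed_view_hides_truth_columns(self, truth_cohort):
        obs = truth_cohort.observed()
        frame = obs.to_frame()
        for hidden in ("U", "D", "Z0", "Z1", "Y0", "Y1", "stratum"):
            assert hidden not in frame.columns


class TestTruthSummaries:
    def test_empirical_sace_hand_counts(self):
        """Always-survivors with Y1 20/120 and Y0 30/120 positive:
        ln{(20/100)/(30/90)} = ln 0.6."""
        n = 120
        from sacekit.simulate import assemble_observed
        Y1 = np.r_[np.ones(20), np.zeros(100)]
        Y0 = np.r_[np.ones(30), np.zeros(90)]
        c = assemble_observed(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n),
                              np.ones(n, dtype=int), np.ones(n, dtype=int),
                              np.ones(n, dtype=int), Y0, Y1, np.ones(n))
        assert empirical_sace(c) == pytest.approx(math.log(0.6), abs=1e-12)

    def test_empirical_tau_hand_fixture(self):
        from sacekit.io import make_fixture
        assert empirical_tau(make_fixture("tau-3")) == pytest.approx(3.0)

    def test_tau_undefined_without_compliant_survivors(self):
        from sacekit.io import make_fixture
        c = make_fixture("strata-basic")
        # strata-basic has CS rows but all Y1 = 0 there -> zero cell -> NaN
        assert math.isnan(empirical_tau(c))


class TestCalibration:
    def test_null_target_calibrates_to_null(self, default_config):
        beta = calibrate_exposure_coefficient(default_config, target_sace_or=1.0,
                                              n_calib=200_000)
        assert abs(beta) < 0.002

    def test_monotone_in_target(self, default_config):
        betas = [calibrate_exposure_coefficient(default_config, target_sace_or=t,
                                                n_calib=150_000)
                 for t in (0.4, 0.6, 0.9)]
        assert betas[0] < betas[1] < betas[2]

    def test_recovery_on_fresh_draws(self, calibrated_default):
        cfg, beta_A = calibrated_default
        cohort = simulate_cohort(cfg.with_(n_participants=400_000), beta_A,
                                 np.random.default_rng(11))
        assert empirical_sace(cohort) == pytest.approx(math.log(0.6), abs=0.02)

    def test_invalid_target_rejected(self, default_config):
        with pytest.raises(CalibrationError):
            calibrate_exposure_coefficient(default_config, target_sace_or=-1.0,
                                           n_calib=1000)
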