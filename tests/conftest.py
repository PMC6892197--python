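import numpy as np
import pytest

from sacekit.config import ScenarioConfig
from sacekit.simulate import calibrate_exposure_coefficient, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    """Default scenario: alpha_UZ = ln 2, beta_UY = 0, valid monotonicity."""
    return ScenarioConfig()


@pytest.fixture(scope="session")
def calibrated_default(default_config):
    """(config, beta_A) for the default scenario; calibration shared session-wide."""
    beta_A = calibrate_exposure_coefficient(default_config, n_calib=400_000)
    return default_config, beta_A


@pytest.fixture(scope="session")
def truth_cohort(calibrated_default):
    """One N=10,000 simulated truth table at the default scenario."""
    cfg, beta_A = calibrated_default
    return simulate_cohort(cfg, beta_A, np.random.default_rng(1234))


@pytest.fixture(scope="session")
def observed_cohort(truth_cohort):
    return truth_cohort.observed()
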