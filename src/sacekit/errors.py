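"""Exception hierarchy shared across sacekit."""


class SacekitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SacekitError):
    """Invalid scenario configuration (bad probability, range, or coefficient block)."""


class EstimationError(SacekitError):
    """Base class for failures inside an estimator pipeline."""


class ConvergenceError(EstimationError):
    """Logistic fit failed to converge (separation or ill-conditioning).

    Carries a ``diagnostics`` dict with the iteration count, final score norm
    and coefficient vector so callers can log the failure mode.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SingularDesignError(EstimationError):
    """Design matrix is rank-deficient for the requested fit."""


class DegenerateDataError(EstimationError):
    """Data cannot support the requested quantity (empty stratum, zero cell)."""


class CalibrationError(SacekitError):
    """Exposure-coefficient calibration could not bracket the target effect."""


class IntegrityError(SacekitError):
    """Cohort file violates the observed-data contract (e.g. outcome for a non-survivor)."""
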