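"""Scenario configuration for the principal-stratification simulator.

A scenario is defined by the strength and direction of an unmeasured
survival-outcome confounder (``alpha_UZ`` on survival, ``beta_UY`` on the
outcome, both log odds ratios), whether the exposure's effect on survival is
monotone (no defiant-survivors), and the coefficient blocks of the four
generating models.  The canonical study grid crosses
``alpha_UZ in {ln 0.5, ln 2}`` with ``beta_UY in {ln 0.5, 0, ln 2}`` and
monotonicity {valid, violated} — 12 scenarios.

Default coefficient values are declared here once.  They aim for a cohort
that looks like a large ageing-cohort study: ~50% exposed, ~84-94% survival
to follow-up, ~70% attendance among survivors, and a rare-to-moderate
(~10%) outcome among unexposed survivors.  Covariate effects on the outcome
are kept modest so that the covariate-conditional and marginal odds ratios
nearly coincide (odds ratios are non-collapsible; large covariate effects
would open a gap between the two even without confounding).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import ConfigurationError

__all__ = [
    "CovariateDist",
    "ExposureCoefs",
    "SurvivalCoefs",
    "OutcomeCoefs",
    "AttendanceCoefs",
    "ScenarioConfig",
    "scenario_grid",
    "parse_config",
    "parse_value",
    "MONOTONICITY_VALID",
    "MONOTONICITY_VIOLATED",
]

MONOTONICITY_VALID = "valid"
MONOTONICITY_VIOLATED = "violated"


@dataclass(frozen=True)
class CovariateDist:
    """Baseline covariate distribution: Bernoulli probabilities and age range.

    Age (V2) is mean-centred, Uniform(-age_range, age_range) in years.
    """

    p_sex: float = 0.5
    p_genotype: float = 0.5
    p_residence: float = 0.5
    age_range: float = 10.0

    def validate(self):
        for name in ("p_sex", "p_genotype", "p_residence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.age_range <= 0:
            raise ConfigurationError(f"age_range={self.age_range} must be positive")


@dataclass(frozen=True)
class ExposureCoefs:
    """Logit model for exposure A given sex and age (U, D excluded by design)."""

    intercept: float = -0.2
    sex: float = 0.4
    age: float = 0.04


@dataclass(frozen=True)
class SurvivalCoefs:
    """Logit model for survival Z(a): intercept + exposure*a + sex + age (+ alpha_UZ*U).

    The exposure coefficient is large by design: the survivor average causal
    effect is the relevant estimand precisely when the exposure strongly
    affects survival, and the compliant-survivor stratum it creates is what
    drives survival bias in the confounded scenarios.
    """

    intercept: float = 0.8
    exposure: float = 1.3
    sex: float = 0.3
    age: float = -0.03


@dataclass(frozen=True)
class OutcomeCoefs:
    """Logit model for the outcome Y(a): intercept + beta_A*a + sex + age (+ beta_UY*U).

    ``beta_A`` is not stored here — it is calibrated per scenario so the
    marginal always-survivor odds ratio hits ``target_sace_or``.
    """

    intercept: float = -2.4
    sex: float = 0.2
    age: float = 0.02


@dataclass(frozen=True)
class AttendanceCoefs:
    """Logit model for attendance R among survivors: A, sex, age and residence D."""

    intercept: float = 1.1
    exposure: float = 0.2
    sex: float = 0.15
    age: float = -0.02
    residence: float = math.log(0.5)


#: alpha_UZ / beta_UY values of the canonical 12-scenario grid.
GRID_ALPHA_UZ = (math.log(0.5), math.log(2.0))
GRID_BETA_UY = (math.log(0.5), 0.0, math.log(2.0))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario."""

    alpha_UZ: float = math.log(2.0)
    beta_UY: float = 0.0
    monotonicity: str = MONOTONICITY_VALID
    n_participants: int = 10_000
    n_reps: int = 1200
    target_sace_or: float = 0.6
    covariates: CovariateDist = field(default_factory=CovariateDist)
    exposure: ExposureCoefs = field(default_factory=ExposureCoefs)
    survival: SurvivalCoefs = field(default_factory=SurvivalCoefs)
    outcome: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    attendance: AttendanceCoefs = field(default_factory=AttendanceCoefs)
    base_seed: int = 20191203
    scenario_index: int = 0
    # Coupling for Z(0) | Z(1)=1 under valid monotonicity:
    # "conditional" (default) draws Bernoulli(p0) among survivors-under-
    # exposure — the model probability evaluated at a=0 within that subset;
    # "marginal" draws Bernoulli(p0/p1), the unique monotone coupling that
    # preserves the a=0 marginal P(Z(0)=1) = p0.
    monotone_coupling: str = "conditional"
    # Enter the unmeasured confounder centred (alpha_UZ * (U - p_genotype))
    # in the survival model, so that marginal mortality is comparable across
    # scenarios that differ only in the confounder's direction of effect.
    center_survival_confounder: bool = True

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if not self.target_sace_or > 0:
            raise ConfigurationError("target_sace_or must be positive")
        if self.monotonicity not in (MONOTONICITY_VALID, MONOTONICITY_VIOLATED):
            raise ConfigurationError(
                f"monotonicity={self.monotonicity!r}: expected "
                f"'{MONOTONICITY_VALID}' or '{MONOTONICITY_VIOLATED}'"
            )
        if self.monotonicity == MONOTONICITY_VALID and self.survival.exposure < 0:
            raise ConfigurationError(
                "monotone design requires a non-negative exposure effect on survival"
            )
        if self.monotone_coupling not in ("conditional", "marginal"):
            raise ConfigurationError(
                f"monotone_coupling={self.monotone_coupling!r}: expected "
                "'conditional' or 'marginal'"
            )
        self.covariates.validate()

    @property
    def label(self) -> str:
        return (
            f"aUZ={math.exp(self.alpha_UZ):g}_bUY={math.exp(self.beta_UY):g}"
            f"_{self.monotonicity}"
        )

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def scenario_grid(base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """The canonical 12-scenario grid, in deterministic order.

    Order: alpha_UZ (ln 0.5, ln 2) x beta_UY (ln 0.5, 0, ln 2) x
    monotonicity (valid, violated); ``scenario_index`` runs 0..11.
    """
    base = base or ScenarioConfig()
    grid = []
    idx = 0
    for a in GRID_ALPHA_UZ:
        for b in GRID_BETA_UY:
            for m in (MONOTONICITY_VALID, MONOTONICITY_VIOLATED):
                grid.append(
                    base.with_(alpha_UZ=a, beta_UY=b, monotonicity=m, scenario_index=idx)
                )
                idx += 1
    return grid


_LN_RE = re.compile(r"^\s*ln\(\s*([0-9.eE+-]+)\s*\)\s*$")


def parse_value(v):
    """Parse a numeric config entry, supporting the ``"ln(x)"`` shorthand."""
    if isinstance(v, str):
        m = _LN_RE.match(v)
        if m:
            return math.log(float(m.group(1)))
        try:
            return float(v)
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse numeric value {v!r}") from exc
    return v


_BLOCKS = {
    "covariates": CovariateDist,
    "exposure": ExposureCoefs,
    "survival": SurvivalCoefs,
    "outcome": OutcomeCoefs,
    "attendance": AttendanceCoefs,
}
_SCALAR_KEYS = {
    "alpha_UZ", "beta_UY", "monotonicity", "n_participants", "n_reps",
    "target_sace_or", "base_seed", "scenario_index", "monotone_coupling",
    "center_survival_confounder",
}


def _build_config(raw: dict) -> ScenarioConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    kwargs = {}
    for key, val in raw.items():
        if key in _BLOCKS:
            cls = _BLOCKS[key]
            if not isinstance(val, dict):
                raise ConfigurationError(f"block {key!r} must be a mapping")
            allowed = set(cls.__dataclass_fields__)
            bad = set(val) - allowed
            if bad:
                raise ConfigurationError(
                    f"unknown key(s) {sorted(bad)} in block {key!r}; allowed: {sorted(allowed)}"
                )
            kwargs[key] = cls(**{k: parse_value(v) for k, v in val.items()})
        elif key in _SCALAR_KEYS:
            if key in ("monotonicity", "monotone_coupling"):
                kwargs[key] = val
            elif key in ("n_participants", "n_reps", "base_seed", "scenario_index"):
                iv = int(parse_value(val))
                if iv < 0:
                    raise ConfigurationError(f"{key}={iv} must be non-negative")
                kwargs[key] = iv
            elif key == "center_survival_confounder":
                kwargs[key] = bool(val)
            else:
                kwargs[key] = float(parse_value(val))
        else:
            raise ConfigurationError(
                f"unknown config key {key!r}; allowed: "
                f"{sorted(_SCALAR_KEYS | set(_BLOCKS))}"
            )
    return ScenarioConfig(**kwargs)


def parse_config(path) -> ScenarioConfig:
    """Read a scenario configuration from a JSON or YAML file.

    Unknown keys are rejected with a message naming the offending key.
    Values of the form ``"ln(x)"`` are converted to natural logs.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = yaml.safe_load(text)
    return _build_config(raw)
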