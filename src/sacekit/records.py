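"""Lightweight result records shared by the estimators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EstimateRecord"]


@dataclass
class EstimateRecord:
    """One SACE estimate on the log odds-ratio scale.

    ``method`` is ``"msm"`` or ``"sens@<tau>"``.  Confidence bounds are NaN
    unless a bootstrap was run.  ``extra`` carries method-specific
    diagnostics (weight summaries, marginal quantities, resample failures).
    """

    method: str
    log_or: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    converged: bool = True
    n_used: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    def covers(self, truth_log_or: float) -> bool:
        return bool(self.ci_low <= truth_log_or <= self.ci_high)
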