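"""Cohort containers: the full potential-outcome truth table and the analyst view.

Conventions for partially defined columns
-----------------------------------------
Outcomes of participants who die before follow-up are *undefined*, not
missing: ``Y(a)`` exists only where ``Z(a) = 1``, attendance ``R`` exists only
for survivors, and the observed outcome exists only for surviving attenders.
Internally, undefined and missing entries are both stored as ``NaN`` in float
arrays; the distinction is carried by ``Z`` and ``R`` and re-derived on
demand (``Z=0`` -> undefined; ``Z=1, R=0`` -> missing).  On disk, undefined is
an empty field and missing is the literal token ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError

__all__ = [
    "AS", "CS", "DS", "NS", "STRATUM_LABELS",
    "PotentialCohort", "ObservedCohort", "assign_strata",
]

# Principal strata codes, by joint potential survival (Z(0), Z(1)).
AS, CS, DS, NS = 0, 1, 2, 3
STRATUM_LABELS = np.array(["AS", "CS", "DS", "NS"])


def assign_strata(Z0, Z1) -> np.ndarray:
    """Map joint potential survival to principal strata.

    (1,1) -> always-survivor, (0,1) -> compliant-survivor,
    (1,0) -> defiant-survivor, (0,0) -> never-survivor.
    """
    Z0 = np.asarray(Z0)
    Z1 = np.asarray(Z1)
    if not (np.isin(Z0, (0, 1)).all() and np.isin(Z1, (0, 1)).all()):
        raise ValueError("Z0 and Z1 must be binary")
    # AS=0: Z0=1,Z1=1 ; CS=1: 0,1 ; DS=2: 1,0 ; NS=3: 0,0
    return np.where(
        Z1 == 1, np.where(Z0 == 1, AS, CS), np.where(Z0 == 1, DS, NS)
    ).astype(np.int8)


@dataclass
class ObservedCohort:
    """The analyst-visible cohort: no U, D, strata or potential outcomes."""

    V1: np.ndarray   # sex, binary
    V2: np.ndarray   # age, mean-centred years
    A: np.ndarray    # exposure, binary
    Z: np.ndarray    # survival to follow-up, binary
    R: np.ndarray    # attendance; NaN where Z=0 (undefined)
    Y: np.ndarray    # observed outcome; NaN where Z=0 (undefined) or R=0 (missing)

    def __post_init__(self):
        n = len(self.A)
        for name in ("V1", "V2", "Z", "R", "Y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has wrong length")

    @property
    def n(self) -> int:
        return len(self.A)

    @property
    def n_exposed(self) -> int:
        return int(np.sum(self.A == 1))

    @property
    def n_survivors(self) -> int:
        return int(np.sum(self.Z == 1))

    @property
    def survivor_mask(self) -> np.ndarray:
        return self.Z == 1

    @property
    def attender_mask(self) -> np.ndarray:
        """Survivors who attended follow-up."""
        return (self.Z == 1) & (self.R == 1)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Complete cases: surviving attenders with an observed outcome."""
        return self.attender_mask & ~np.isnan(self.Y)

    def subset(self, idx) -> "ObservedCohort":
        return ObservedCohort(*(np.asarray(c)[idx] for c in
                                (self.V1, self.V2, self.A, self.Z, self.R, self.Y)))

    def resample(self, rng) -> "ObservedCohort":
        """Nonparametric bootstrap resample of baseline participants."""
        return self.subset(rng.integers(0, self.n, size=self.n))

    def validate(self):
        if np.any((self.Z == 0) & ~np.isnan(self.Y)):
            rows = np.where((self.Z == 0) & ~np.isnan(self.Y))[0]
            raise IntegrityError(
                f"outcome recorded for non-survivor row(s) {rows[:5].tolist()}"
            )
        if np.any((self.Z == 0) & ~np.isnan(self.R)):
            rows = np.where((self.Z == 0) & ~np.isnan(self.R))[0]
            raise IntegrityError(
                f"attendance recorded for non-survivor row(s) {rows[:5].tolist()}"
            )
        for name, col in (("V1", self.V1), ("A", self.A), ("Z", self.Z)):
            vals = np.asarray(col)
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                raise IntegrityError(
                    f"non-binary value in column {name} at row {int(np.where(bad)[0][0])}"
                )
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n),
            "V1": self.V1.astype(int), "V2": self.V2,
            "A": self.A.astype(int), "Z": self.Z.astype(int),
            "R": self.R, "Y_obs": self.Y,
        })


@dataclass
class PotentialCohort:
    """Simulated truth: covariates (incl. unmeasured U, D), both potential
    survival/outcome values, principal stratum, and the realized observables."""

    V1: np.ndarray
    V2: np.ndarray
    U: np.ndarray    # unmeasured survival-outcome confounder (genotype)
    D: np.ndarray    # unmeasured attendance predictor (residence)
    A: np.ndarray
    Z0: np.ndarray   # Z(a=0)
    Z1: np.ndarray   # Z(a=1)
    stratum: np.ndarray
    Y0: np.ndarray   # Y(a=0); NaN where Z(a=0)=0 (undefined)
    Y1: np.ndarray   # Y(a=1); NaN where Z(a=1)=0
    Z: np.ndarray
    R: np.ndarray
    Y: np.ndarray    # observed outcome

    @property
    def n(self) -> int:
        return len(self.A)

    def stratum_counts(self) -> dict:
        return {STRATUM_LABELS[s]: int(np.sum(self.stratum == s))
                for s in (AS, CS, DS, NS)}

    def observed(self) -> ObservedCohort:
        """Drop everything the analyst cannot see."""
        return ObservedCohort(V1=self.V1, V2=self.V2, A=self.A,
                              Z=self.Z, R=self.R, Y=self.Y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n),
            "V1": self.V1.astype(int), "V2": self.V2,
            "U": self.U.astype(int), "D": self.D.astype(int),
            "A": self.A.astype(int),
            "Z0": self.Z0.astype(int), "Z1": self.Z1.astype(int),
            "stratum": STRATUM_LABELS[self.stratum],
            "Y0": self.Y0, "Y1": self.Y1,
            "Z": self.Z.astype(int), "R": self.R, "Y_obs": self.Y,
        })
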