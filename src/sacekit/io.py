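"""Cohort file I/O, run manifests, and tiny deterministic test fixtures.

CSV is the single interchange format: UTF-8, comma-delimited, mandatory
header.  Missing outcomes among survivors are written as the literal token
``NA``; *undefined* entries (outcomes of the dead, attendance of the dead,
potential outcomes where the matching potential survival is 0) are written
as empty fields.  Reading re-derives the distinction from Z and R and
enforces it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .cohort import STRATUM_LABELS, ObservedCohort, PotentialCohort
from .errors import IntegrityError

__all__ = [
    "write_cohort", "read_cohort", "make_fixture", "RunManifest",
    "TRUTH_COLUMNS", "OBSERVED_COLUMNS",
]

NA_TOKEN = "NA"
TRUTH_COLUMNS = ["id", "V1", "V2", "U", "D", "A", "Z0", "Z1", "stratum",
                 "Y0", "Y1", "Z", "R", "Y_obs"]
OBSERVED_COLUMNS = ["id", "V1", "V2", "A", "Z", "R", "Y_obs"]


def _format_partial(values, defined, missing=None):
    """Format a float column: empty where undefined, NA where missing."""
    out = []
    for i, v in enumerate(values):
        if not defined[i]:
            out.append("")
        elif missing is not None and missing[i]:
            out.append(NA_TOKEN)
        else:
            out.append(str(int(v)) if float(v).is_integer() else repr(float(v)))
    return out


def write_cohort(cohort, path, view: str = "observed"):
    """Write a cohort to CSV in the documented truth or observed layout."""
    if view == "truth":
        if not isinstance(cohort, PotentialCohort):
            raise TypeError("truth view requires a PotentialCohort")
        surv = cohort.Z == 1
        miss = surv & (cohort.R == 0)
        df = pd.DataFrame({
            "id": np.arange(cohort.n),
            "V1": cohort.V1.astype(int), "V2": cohort.V2,
            "U": cohort.U.astype(int), "D": cohort.D.astype(int),
            "A": cohort.A.astype(int),
            "Z0": cohort.Z0.astype(int), "Z1": cohort.Z1.astype(int),
            "stratum": STRATUM_LABELS[cohort.stratum],
            "Y0": _format_partial(np.nan_to_num(cohort.Y0), cohort.Z0 == 1),
            "Y1": _format_partial(np.nan_to_num(cohort.Y1), cohort.Z1 == 1),
            "Z": cohort.Z.astype(int),
            "R": _format_partial(np.nan_to_num(cohort.R), surv),
            "Y_obs": _format_partial(np.nan_to_num(cohort.Y), surv, missing=miss),
        })
    elif view == "observed":
        obs = cohort.observed() if isinstance(cohort, PotentialCohort) else cohort
        surv = obs.Z == 1
        miss = surv & (obs.R == 0)
        df = pd.DataFrame({
            "id": np.arange(obs.n),
            "V1": obs.V1.astype(int), "V2": obs.V2,
            "A": obs.A.astype(int), "Z": obs.Z.astype(int),
            "R": _format_partial(np.nan_to_num(obs.R), surv),
            "Y_obs": _format_partial(np.nan_to_num(obs.Y), surv, missing=miss),
        })
    else:
        raise ValueError(f"unknown view {view!r}")
    df.to_csv(path, index=False)


def _parse_partial(col, *, na_is_nan=True):
    vals = np.full(len(col), np.nan)
    for i, raw in enumerate(col):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        s = str(raw).strip()
        if s == "" or s.lower() == "nan":
            continue
        if s == NA_TOKEN:
            if not na_is_nan:
                raise IntegrityError(f"unexpected NA token at row {i}")
            continue
        vals[i] = float(s)
    return vals


def _check_binary(df, name):
    vals = pd.to_numeric(df[name], errors="coerce").to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        raise IntegrityError(
            f"malformed binary column {name!r}: value {vals[bad][0]!r} "
            f"at row {int(np.where(bad)[0][0])}")
    return vals.astype(np.int8)


def read_cohort(path, view: str = "observed"):
    """Read a cohort CSV as the requested view.

    A truth-layout file requested as ``view="observed"`` has its hidden
    columns (U, D, potential outcomes, stratum) dropped.  Integrity rules:
    Y_obs or R present for a non-survivor row is an error; unknown columns
    only warn.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    have = set(df.columns)
    is_truth_file = {"U", "Z0", "Z1"} <= have
    need = set(TRUTH_COLUMNS if view == "truth" else OBSERVED_COLUMNS) - {"id"}
    if view == "truth" and not is_truth_file:
        raise IntegrityError("file lacks truth columns (U, Z0, Z1, ...)")
    missing_cols = need - have - ({"U", "D", "Z0", "Z1", "stratum", "Y0", "Y1"}
                                  if view == "observed" else set())
    if missing_cols:
        raise IntegrityError(f"missing column(s) {sorted(missing_cols)}")
    import warnings
    unknown = have - set(TRUTH_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown column(s) {sorted(unknown)}", RuntimeWarning)
    if view == "observed" and is_truth_file:
        hidden = sorted(have - set(OBSERVED_COLUMNS))
        warnings.warn(f"truth-layout file: dropping hidden column(s) {hidden}",
                      RuntimeWarning)

    V1 = _check_binary(df, "V1")
    A = _check_binary(df, "A")
    Z = _check_binary(df, "Z")
    V2 = pd.to_numeric(df["V2"]).to_numpy(float)
    R = _parse_partial(df["R"], na_is_nan=False)
    Y = _parse_partial(df["Y_obs"])
    for nm, col in (("R", R), ("Y_obs", Y)):
        bad = (Z == 0) & ~np.isnan(col)
        if bad.any():
            raise IntegrityError(
                f"{nm} recorded for non-survivor row {int(np.where(bad)[0][0])}")
    obs = ObservedCohort(V1=V1, V2=V2, A=A, Z=Z, R=R, Y=Y).validate()
    if view == "observed":
        return obs
    U = _check_binary(df, "U")
    D = _check_binary(df, "D")
    Z0 = _check_binary(df, "Z0")
    Z1 = _check_binary(df, "Z1")
    lbl = df["stratum"].to_numpy()
    try:
        codes = np.array([{"AS": 0, "CS": 1, "DS": 2, "NS": 3}[s] for s in lbl],
                         dtype=np.int8)
    except KeyError as exc:
        raise IntegrityError(f"unknown stratum label {exc}") from exc
    Y0 = _parse_partial(df["Y0"])
    Y1 = _parse_partial(df["Y1"])
    for nm, col, zz in (("Y0", Y0, Z0), ("Y1", Y1, Z1)):
        bad = (zz == 0) & ~np.isnan(col)
        if bad.any():
            raise IntegrityError(
                f"{nm} defined where the matching potential survival is 0 "
                f"(row {int(np.where(bad)[0][0])})")
    return PotentialCohort(V1=V1, V2=V2, U=U, D=D, A=A, Z0=Z0, Z1=Z1,
                           stratum=codes, Y0=Y0, Y1=Y1, Z=Z, R=R, Y=Y)


# ---------------------------------------------------------------------------
# Deterministic fixtures for oracle tests


def _potential(V1, V2, U, D, A, Z0, Z1, Y0, Y1, R):
    from .simulate import assemble_observed
    arr = lambda x, dt=np.int8: np.asarray(x, dtype=dt)
    return assemble_observed(arr(V1), np.asarray(V2, float), arr(U), arr(D),
                             arr(A), arr(Z0), arr(Z1),
                             np.asarray(Y0, float), np.asarray(Y1, float),
                             np.asarray(R, float))


def make_fixture(name: str):
    """Hand-constructed cohorts with exactly known strata counts and estimates.

    - ``strata-basic``: 10 rows, strata counts AS=4, CS=3, DS=2, NS=1.
    - ``logistic-2x2``: 50 surviving attenders forming the exposure-outcome
      table (a,b,c,d)=(10,20,15,5), logistic slope ln(ad/bc) = ln(1/6).
    - ``tau-3``: compliant-survivor odds of Y(1) equal 1, always-survivor
      odds 1/3, so tau = 3 exactly.
    """
    nan = float("nan")
    if name == "strata-basic":
        Z0 = [1, 1, 1, 1, 0, 0, 0, 1, 1, 0]
        Z1 = [1, 1, 1, 1, 1, 1, 1, 0, 0, 0]
        n = len(Z0)
        Y0 = [0 if z else nan for z in Z0]
        Y1 = [0 if z else nan for z in Z1]
        return _potential([0] * n, [0.0] * n, [0] * n, [0] * n, [1] * n,
                          Z0, Z1, Y0, Y1,
                          [1 if (a and z1) or (not a and z0) else nan
                           for a, z0, z1 in zip([1] * n, Z0, Z1)])
    if name == "logistic-2x2":
        A, Y = [], []
        for a, y, count in ((1, 1, 10), (1, 0, 20), (0, 1, 15), (0, 0, 5)):
            A += [a] * count
            Y += [y] * count
        n = len(A)
        return _potential([0] * n, [0.0] * n, [0] * n, [0] * n, A,
                          [1] * n, [1] * n, Y, Y, [1.0] * n)
    if name == "tau-3":
        # 4 compliant-survivors with Y1 = (1,1,0,0): odds 1.
        # 4 always-survivors  with Y1 = (1,0,0,0): odds 1/3.  tau = 3.
        Z0 = [0, 0, 0, 0, 1, 1, 1, 1]
        Z1 = [1] * 8
        Y1 = [1, 1, 0, 0, 1, 0, 0, 0]
        Y0 = [nan] * 4 + [1, 0, 0, 0]
        n = 8
        return _potential([0] * n, [0.0] * n, [0] * n, [0] * n, [1] * n,
                          Z0, Z1, Y0, Y1, [1.0] * n)
    raise KeyError(f"unknown fixture {name!r}; available: "
                   "strata-basic, logistic-2x2, tau-3")


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    """Reproducibility record for a study run: identical manifest inputs must
    reproduce identical estimate files."""

    base_seed: int
    preset: str
    scenario_labels: list
    config_hash: str
    package_version: str
    started: str = ""
    finished: str = ""
    failure_counts: dict = field(default_factory=dict)

    @staticmethod
    def config_digest(configs) -> str:
        payload = json.dumps([c.to_dict() for c in configs], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stamp_start(self):
        self.started = datetime.now(timezone.utc).isoformat()

    def stamp_end(self):
        self.finished = datetime.now(timezone.utc).isoformat()

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
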