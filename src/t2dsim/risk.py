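"""Quarterly risk-factor dynamics.

Each of the nine risk factors follows a linear AR(1) update:

    x[t+1] = intercept + lag1 * x[t] + sum_k beta_k * covariate_k
             + time_coef * t + regimen_effect + offset[t]  (+ noise)

where the regimen effect is the registry's combined additive shift for the
current quarter's therapy, ``offset`` is an optional recalibration schedule,
and the Gaussian innovation (sd ``resid_sd``) is drawn only in stochastic
mode.  Expected mode is fully deterministic and consumes no randomness.
Outputs are clipped at documented physiologic floors; clipping events are
counted on the equation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import RISK_FACTORS, RiskFactorVector
from .effects import EffectsRegistry, effect_matrix
from .errors import ConfigurationError
from .pathways import HORIZON_QUARTERS, RegimenCode

__all__ = [
    "COVARIATES",
    "FLOORS",
    "RiskEquation",
    "OffsetSchedule",
    "EquationSet",
    "apply_offsets",
    "update_risk_factors",
    "default_risk_equations",
]

#: Baseline covariates an equation may load on.  ``sex_female``,
#: ``cvd_history``, ``statin`` and ``bp_lowering`` are 0/1 indicators.
COVARIATES = ("age", "sex_female", "years_since_diagnosis", "cvd_history",
              "statin", "bp_lowering")

#: Physiologic floors applied after every update (per factor unit).
FLOORS = {
    "hba1c": 3.0,
    "bmi": 12.0,
    "sbp": 60.0,
    "dbp": 30.0,
    "hdl": 10.0,
    "ldl": 10.0,
    "total_cholesterol": 50.0,
    "triglycerides_nonfasting": 20.0,
    # strictly positive so a floored state remains a valid risk-factor vector
    "egfr": 1.0,
}


@dataclass(frozen=True)
class RiskEquation:
    target: str
    intercept: float
    lag1: float
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    time_coef: float = 0.0
    resid_sd: float = 0.0

    def __post_init__(self):
        if self.target not in RISK_FACTORS:
            raise ConfigurationError(f"unknown risk factor {self.target!r}")
        if not np.isfinite(self.lag1):
            raise ConfigurationError("lag-1 coefficient must be finite")
        if self.resid_sd < 0:
            raise ConfigurationError("residual sd must be >= 0")
        unknown = set(self.covariate_coefs) - set(COVARIATES)
        if unknown:
            raise ConfigurationError(f"unknown covariates {sorted(unknown)}")


@dataclass(frozen=True)
class OffsetSchedule:
    """Additive recalibration offset per quarter for one risk factor."""

    target: str
    offsets: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "offsets",
                           np.asarray(self.offsets, dtype=float))

    def at(self, quarter: int) -> float:
        return float(self.offsets[quarter])


class EquationSet:
    """All nine risk equations plus any attached offset schedules."""

    def __init__(self, equations: Mapping[str, RiskEquation],
                 offsets: Mapping[str, OffsetSchedule] | None = None,
                 horizon: int = HORIZON_QUARTERS):
        missing = set(RISK_FACTORS) - set(equations)
        if missing:
            raise ConfigurationError(
                f"missing risk equation(s) for: {', '.join(sorted(missing))}")
        self.equations = dict(equations)
        self.horizon = horizon
        self.offsets: dict[str, OffsetSchedule] = {}
        self.clip_count = 0
        if offsets:
            for target, sched in offsets.items():
                self._check_schedule(sched)
                self.offsets[target] = sched

    def _check_schedule(self, sched: OffsetSchedule) -> None:
        if sched.target not in RISK_FACTORS:
            raise ConfigurationError(f"unknown risk factor {sched.target!r}")
        if len(sched.offsets) != self.horizon:
            raise ConfigurationError(
                f"offset schedule for {sched.target!r} has "
                f"{len(sched.offsets)} quarters, horizon is {self.horizon}")

    def with_offsets(self, schedules) -> "EquationSet":
        """Attach (or replace) offset schedules; idempotent."""
        if isinstance(schedules, OffsetSchedule):
            schedules = [schedules]
        if isinstance(schedules, Mapping):
            schedules = list(schedules.values())
        new = dict(self.offsets)
        for sched in schedules:
            self._check_schedule(sched)
            new[sched.target] = sched
        return EquationSet(self.equations, new, self.horizon)

    def offset_vector(self, quarter: int) -> np.ndarray:
        out = np.zeros(len(RISK_FACTORS))
        for j, f in enumerate(RISK_FACTORS):
            if f in self.offsets:
                out[j] = self.offsets[f].at(quarter)
        return out

    # coefficient arrays for the vectorised engine -------------------------
    def arrays(self):
        k = len(RISK_FACTORS)
        intercept = np.array([self.equations[f].intercept for f in RISK_FACTORS])
        lag1 = np.array([self.equations[f].lag1 for f in RISK_FACTORS])
        time_coef = np.array([self.equations[f].time_coef for f in RISK_FACTORS])
        beta = np.zeros((len(COVARIATES), k))
        for j, f in enumerate(RISK_FACTORS):
            for c, v in self.equations[f].covariate_coefs.items():
                beta[COVARIATES.index(c), j] = v
        resid = np.array([self.equations[f].resid_sd for f in RISK_FACTORS])
        floors = np.array([FLOORS[f] for f in RISK_FACTORS])
        return intercept, lag1, time_coef, beta, resid, floors


def apply_offsets(equations: EquationSet, schedules) -> EquationSet:
    """Functional alias of :meth:`EquationSet.with_offsets`: returns a new
    equation set with the recalibration schedules attached (replacing any
    existing schedule for the same factor).  A zero schedule is a no-op on
    predictions."""
    return equations.with_offsets(schedules)


def advance_states(X: np.ndarray, cov: np.ndarray, regimen_codes: np.ndarray,
                   eqset: EquationSet, effect_lookup: np.ndarray,
                   quarter: int, mode: str = "expected",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Vectorised one-quarter update of an (n, 9) state matrix.

    ``cov`` is (n, len(COVARIATES)); ``effect_lookup`` is the
    (n_regimens, 9) additive-shift matrix from :func:`effects.effect_matrix`.
    """
    intercept, lag1, time_coef, beta, resid, floors = eqset.arrays()
    nxt = (intercept[None, :] + lag1[None, :] * X + cov @ beta
           + time_coef[None, :] * quarter
           + effect_lookup[regimen_codes.astype(int)]
           + eqset.offset_vector(quarter)[None, :])
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an RNG")
        nxt = nxt + rng.standard_normal(X.shape) * resid[None, :]
    elif mode != "expected":
        raise ValueError(f"unknown mode {mode!r}")
    clipped = nxt < floors[None, :]
    eqset.clip_count += int(clipped.sum())
    return np.maximum(nxt, floors[None, :])


def update_risk_factors(state: RiskFactorVector, profile, regimen: RegimenCode,
                        equations: EquationSet, registry: EffectsRegistry,
                        mode: str = "expected", quarter: int = 0,
                        seed: int | None = None) -> RiskFactorVector:
    """Single-individual one-quarter update (scalar convenience wrapper
    around :func:`advance_states`)."""
    cov = np.array([[
        profile.age,
        1.0 if profile.sex == "female" else 0.0,
        profile.years_since_diagnosis,
        1.0 if profile.cvd_history else 0.0,
        0.0,  # statin / bp flags are timeline-level inputs; zero here
        0.0,
    ]])
    rng = (np.random.default_rng(seed) if mode == "stochastic" else None)
    lookup = effect_matrix(registry, RISK_FACTORS)
    out = advance_states(state.as_array()[None, :], cov,
                         np.array([int(regimen)]), equations, lookup,
                         quarter, mode=mode, rng=rng)
    return RiskFactorVector.from_array(out[0])


# Default equation set: stationary at the published cohort medians under no
# therapy (intercept = (1 - lag1) * median), a common lag of 0.9 per quarter,
# and a deterministic eGFR time decline whose asymptotic slope is about
# -1 mL/min/1.73m2 per year, feeding the kidney-disease pathway.
_DEFAULT_LAG = 0.9
_DEFAULT_MEDIANS = {
    "hba1c": 7.9, "bmi": 31.3, "sbp": 132.0, "dbp": 79.0, "hdl": 42.5,
    "ldl": 81.2, "total_cholesterol": 158.5,
    "triglycerides_nonfasting": 159.4, "egfr": 92.0,
}
_DEFAULT_RESID_SD = {
    "hba1c": 0.15, "bmi": 0.20, "sbp": 2.0, "dbp": 1.5, "hdl": 1.5,
    "ldl": 3.0, "total_cholesterol": 4.0,
    "triglycerides_nonfasting": 10.0, "egfr": 1.5,
}


def default_risk_equations(horizon: int = HORIZON_QUARTERS) -> EquationSet:
    eqs = {}
    for f in RISK_FACTORS:
        eqs[f] = RiskEquation(
            target=f,
            intercept=(1.0 - _DEFAULT_LAG) * _DEFAULT_MEDIANS[f],
            lag1=_DEFAULT_LAG,
            time_coef=-0.025 if f == "egfr" else 0.0,
            resid_sd=_DEFAULT_RESID_SD[f],
        )
    return EquationSet(eqs, horizon=horizon)
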