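"""Per-quarter complication probabilities and incidence aggregation.

Each complication has a logistic model on the 90-day probability scale:

    p = expit( intercept + sum_j beta_j * risk_factor_j + covariate terms
               + time_coef * t + prior_coef * prior_event_count
               + direct regimen log-hazard-ratio )

On the quarterly scale, a logistic link approximates a proportional-hazards
direct effect because per-quarter probabilities are small.  Acute events
(hypoglycaemia, MI, unstable angina, stroke) are recurrent — the probability
of a subsequent event loads on the count of prior events; ESKD and death are
absorbing; eye disease and LEA are modelled as first occurrences.

Cumulative incidence over a horizon is the naive first-event complement
product 1 - prod(1 - p_t), conditional on follow-up — not a cause-specific
competing-risk CIF; expected recurrent-event counts are sums of per-quarter
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .cohort import RISK_FACTORS
from .effects import EVENTS, EffectsRegistry, regimen_effect
from .errors import ConfigurationError, SimulationError
from .pathways import RegimenCode

__all__ = [
    "EVENTS",
    "RECURRENT_EVENTS",
    "ABSORBING_EVENTS",
    "EventModel",
    "EventHistory",
    "event_probability",
    "cumulative_incidence",
    "expected_event_count",
    "default_event_models",
]

RECURRENT_EVENTS = ("hypoglycaemia", "mi", "unstable_angina", "stroke")
ABSORBING_EVENTS = ("eskd", "all_cause_death")

EVENT_COVARIATES = ("age", "sex_female", "years_since_diagnosis", "cvd_history")


@dataclass(frozen=True)
class EventModel:
    name: str
    intercept: float
    factor_coefs: Mapping[str, float] = field(default_factory=dict)
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    time_coef: float = 0.0
    prior_coef: float = 0.0
    absorbing: bool = False
    recurrent: bool = False

    def __post_init__(self):
        if self.name not in EVENTS:
            raise ConfigurationError(f"unknown event {self.name!r}")
        if self.absorbing and self.recurrent:
            raise ConfigurationError(
                f"{self.name}: absorbing and recurrent are mutually exclusive")
        for coefs, allowed in [(self.factor_coefs, RISK_FACTORS),
                               (self.covariate_coefs, EVENT_COVARIATES)]:
            unknown = set(coefs) - set(allowed)
            if unknown:
                raise ConfigurationError(f"unknown terms {sorted(unknown)}")
            if coefs and not np.all(np.isfinite(list(coefs.values()))):
                raise ConfigurationError("coefficients must be finite")

    def linear_predictor(self, state: np.ndarray, covariates: np.ndarray,
                         quarter: int, prior_count) -> np.ndarray:
        """Vectorised linear predictor; ``state`` (n, 9), ``covariates``
        (n, 4), ``prior_count`` scalar or (n,)."""
        lp = np.full(state.shape[0], self.intercept, dtype=float)
        for f, b in self.factor_coefs.items():
            lp += b * state[:, RISK_FACTORS.index(f)]
        for c, b in self.covariate_coefs.items():
            lp += b * covariates[:, EVENT_COVARIATES.index(c)]
        lp += self.time_coef * quarter
        lp += self.prior_coef * np.asarray(prior_count, dtype=float)
        return lp


@dataclass
class EventHistory:
    """Per-individual event bookkeeping for stochastic simulation."""

    counts: dict = field(default_factory=lambda: {e: 0 for e in EVENTS})
    first_quarter: dict = field(default_factory=dict)
    alive: bool = True

    def record(self, event: str, quarter: int) -> None:
        if not self.alive:
            raise SimulationError("cannot record events after death")
        if event not in RECURRENT_EVENTS and self.counts[event] >= 1:
            raise SimulationError(
                f"non-recurrent event {event!r} recorded twice")
        self.counts[event] += 1
        self.first_quarter.setdefault(event, quarter)
        if event == "all_cause_death":
            self.alive = False


def event_probability(state, profile, regimen: RegimenCode, history,
                      model: EventModel, quarter: int,
                      registry: EffectsRegistry) -> float:
    """Per-quarter probability of one event for one individual.

    ``history`` may be an :class:`EventHistory` or a plain mapping of event
    counts.  Raises if the individual is dead or an absorbing event has
    already occurred.
    """
    counts = history.counts if isinstance(history, EventHistory) else dict(history)
    if isinstance(history, EventHistory) and not history.alive:
        raise SimulationError("individual is dead; no event probabilities")
    if model.absorbing and counts.get(model.name, 0) >= 1:
        raise SimulationError(
            f"absorbing event {model.name!r} has already occurred")
    sv = state.as_array() if hasattr(state, "as_array") else np.asarray(state)
    cov = np.array([[
        profile.age,
        1.0 if profile.sex == "female" else 0.0,
        profile.years_since_diagnosis,
        1.0 if profile.cvd_history else 0.0,
    ]])
    prior = counts.get(model.name, 0) if model.recurrent else 0.0
    lp = model.linear_predictor(sv[None, :], cov, quarter, prior)[0]
    lp += regimen_effect(regimen, model.name, registry)
    return float(expit(lp))


def _check_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0):
        raise ValueError("event probabilities must lie in [0, 1]")
    return p


def cumulative_incidence(per_quarter_probs: Sequence[float],
                         up_to_quarter: int | None = None) -> float:
    """P(at least one event by the horizon) = 1 - prod(1 - p_t);
    0 for an empty sequence; nondecreasing in the horizon."""
    p = _check_probs(per_quarter_probs)
    if up_to_quarter is not None:
        p = p[:up_to_quarter]
    if p.size == 0:
        return 0.0
    return float(1.0 - np.prod(1.0 - p))


def expected_event_count(per_quarter_probs: Sequence[float],
                         up_to_quarter: int | None = None) -> float:
    """Expected number of (recurrent) events by the horizon: sum of p_t."""
    p = _check_probs(per_quarter_probs)
    if up_to_quarter is not None:
        p = p[:up_to_quarter]
    return float(np.sum(p))


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

# Baseline quarterly probabilities at the cohort-mean risk profile under no
# therapy, anchored so naive 5-year cumulative incidences sit at magnitudes
# typical of a newly-intensifying T2DM population (eye disease ~23%, kidney
# failure ~3.5%, heart failure ~2.5%, amputation and MI well under 1%).
_BASELINE_QUARTERLY_P = {
    "hypoglycaemia": 0.004,
    "mi": 0.0003,
    "unstable_angina": 0.0003,
    "stroke": 0.0005,
    "hf_hospitalisation": 0.0013,
    "lea": 0.00033,
    "eskd": 0.0018,
    "eye_disease": 0.0128,
    "all_cause_death": 0.0035,
}

_FACTOR_COEFS = {
    "eskd": {"egfr": -0.08, "sbp": 0.01, "hba1c": 0.15},
    "hf_hospitalisation": {"bmi": 0.04, "sbp": 0.02, "hba1c": 0.05},
    "eye_disease": {"hba1c": 0.35, "sbp": 0.01},
    "mi": {"ldl": 0.01, "sbp": 0.02, "hba1c": 0.10},
    "unstable_angina": {"ldl": 0.01, "sbp": 0.02},
    "stroke": {"sbp": 0.025},
    "hypoglycaemia": {},
    "lea": {"hba1c": 0.20, "egfr": -0.02},
    "all_cause_death": {"hba1c": 0.05},
}

_COVARIATE_COEFS = {
    "eskd": {"age": 0.02, "cvd_history": 0.30},
    "hf_hospitalisation": {"age": 0.05, "cvd_history": 0.80},
    "eye_disease": {"years_since_diagnosis": 0.03},
    "mi": {"age": 0.05, "cvd_history": 0.90},
    "unstable_angina": {"age": 0.04, "cvd_history": 0.90},
    "stroke": {"age": 0.06, "cvd_history": 0.70},
    "hypoglycaemia": {"age": 0.02, "years_since_diagnosis": 0.02},
    "lea": {"years_since_diagnosis": 0.03},
    "all_cause_death": {"age": 0.09, "cvd_history": 0.60},
}

_PRIOR_COEFS = {"hypoglycaemia": 0.40, "mi": 0.60,
                "unstable_angina": 0.60, "stroke": 0.50}


def default_event_models(cohort_means: Mapping[str, float] | None = None,
                         covariate_means: Mapping[str, float] | None = None
                         ) -> dict[str, EventModel]:
    """Default logistic event models, intercept-anchored at the cohort mean.

    ``intercept = logit(p0) - beta . mean`` so the linear predictor equals
    ``logit(p0)`` for an average individual under no therapy.  Means default
    to those implied by the default cohort spec.
    """
    if cohort_means is None or covariate_means is None:
        from .cohort import default_cohort_spec
        spec = default_cohort_spec()
        cohort_means = cohort_means or spec.continuous_means()
        covariate_means = covariate_means or spec.covariate_means()
    models = {}
    for name in EVENTS:
        anchor = logit(_BASELINE_QUARTERLY_P[name])
        for f, b in _FACTOR_COEFS[name].items():
            anchor -= b * cohort_means[f]
        for c, b in _COVARIATE_COEFS[name].items():
            anchor -= b * covariate_means[c]
        models[name] = EventModel(
            name=name,
            intercept=float(anchor),
            factor_coefs=_FACTOR_COEFS[name],
            covariate_coefs=_COVARIATE_COEFS[name],
            prior_coef=_PRIOR_COEFS.get(name, 0.0),
            absorbing=name in ABSORBING_EVENTS,
            recurrent=name in RECURRENT_EVENTS,
        )
    return models
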