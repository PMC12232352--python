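"""The quarterly microsimulation and counterfactual treatment contrasts.

Per quarter the loop order is fixed: (1) read the quarter's regimen from the
timeline, (2) compute every complication's probability from the *current*
risk-factor state, (3) advance the risk factors to the next quarter.  An
individual is simulated until censoring, death (stochastic mode only) or
the 31-quarter horizon.

Counterfactual runs build three identical copies of each individual — same
baseline, same second-line duration, same downstream regimens and censoring
— differing only in which metformin dual occupies the second-line quarters.
In stochastic mode the three copies share random numbers (the generator is
seeded identically and draws are aligned by individual index and quarter),
so between-arm differences are free of simulation noise.

Aggregation follows the convention that a horizon-h summary averages over
individuals with at least h of follow-up, with normal-based 95% confidence
intervals (mean +/- 1.96 sd/sqrt(n)); treatment contrasts are paired
within-individual differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import RISK_FACTORS, BaselineProfile, Cohort
from .effects import EVENTS, EffectsRegistry, effect_matrix
from .errors import SimulationError
from .events import (ABSORBING_EVENTS, RECURRENT_EVENTS, EventModel,
                     EVENT_COVARIATES)
from .pathways import (HORIZON_QUARTERS, PathwayTimeline, RegimenCode,
                       SECOND_LINE_DUAL, TimelineSet)
from .risk import COVARIATES, EquationSet, advance_states

__all__ = [
    "CohortSimulation",
    "SimulationResult",
    "ContrastResult",
    "run_cohort",
    "run_individual",
    "run_counterfactuals",
    "run_counterfactual_cohort",
    "counterfactual_timelines",
    "aggregate",
    "contrast",
    "contrast_table",
    "CONTRAST_PAIRS",
]

CONTRAST_PAIRS = (("DPP4i", "SU"), ("SGLT2i", "SU"), ("SGLT2i", "DPP4i"))

Z95 = 1.96


class CohortSimulation:
    """Vectorised per-quarter output for a whole cohort under one assignment.

    ``factors[i, q]`` is individual i's risk-factor state at the start of
    quarter q; ``event_probs[i, q, e]`` the per-quarter probability of event
    e computed from that state (NaN beyond follow-up or after death).
    """

    def __init__(self, ids, arm_label, factors, event_probs, follow_up,
                 censor_quarter, death_quarter, occurrences=None):
        self.ids = np.asarray(ids)
        self.arm_label = arm_label
        self.factors = factors
        self.event_probs = event_probs
        self.follow_up = np.asarray(follow_up)
        self.censor_quarter = np.asarray(censor_quarter)
        self.death_quarter = np.asarray(death_quarter)
        self.occurrences = occurrences

    def __len__(self):
        return len(self.ids)

    @property
    def n_quarters(self):
        return self.factors.shape[1]

    def _event_index(self, event: str) -> int:
        return EVENTS.index(event)

    def cumulative_incidence(self, event: str,
                             horizon_quarters: int | None = None) -> np.ndarray:
        """Per-individual 1 - prod(1 - p_t) over observed quarters up to the
        horizon; nondecreasing in the horizon."""
        p = self.event_probs[:, :, self._event_index(event)]
        if horizon_quarters is not None:
            p = p[:, :horizon_quarters]
        return 1.0 - np.nanprod(1.0 - p, axis=1)

    def expected_count(self, event: str,
                       horizon_quarters: int | None = None) -> np.ndarray:
        p = self.event_probs[:, :, self._event_index(event)]
        if horizon_quarters is not None:
            p = p[:, :horizon_quarters]
        return np.nansum(p, axis=1)

    def level(self, factor: str, quarter: int) -> np.ndarray:
        return self.factors[:, quarter, RISK_FACTORS.index(factor)]

    def individual(self, i: int) -> "SimulationResult":
        T = int(self.follow_up[i])
        return SimulationResult(
            id=str(self.ids[i]),
            second_line_class=self.arm_label
            if isinstance(self.arm_label, str) else str(self.arm_label[i]),
            factors=self.factors[i, :T].copy(),
            event_probs=self.event_probs[i, :T].copy(),
            censor_quarter=(int(self.censor_quarter[i])
                            if self.censor_quarter[i] >= 0 else None),
            death_quarter=(int(self.death_quarter[i])
                           if self.death_quarter[i] >= 0 else None),
        )


@dataclass
class SimulationResult:
    """One individual's simulated trajectories under one assignment."""

    id: str
    second_line_class: str
    factors: np.ndarray        # (T, 9)
    event_probs: np.ndarray    # (T, n_events)
    censor_quarter: int | None
    death_quarter: int | None

    @property
    def n_quarters(self) -> int:
        return len(self.factors)

    def cumulative_incidence(self, event: str,
                             horizon_quarters: int | None = None) -> float:
        p = self.event_probs[:horizon_quarters, EVENTS.index(event)]
        p = p[~np.isnan(p)]
        return float(1.0 - np.prod(1.0 - p)) if p.size else 0.0

    def expected_count(self, event: str,
                       horizon_quarters: int | None = None) -> float:
        p = self.event_probs[:horizon_quarters, EVENTS.index(event)]
        return float(np.nansum(p))


@dataclass
class ContrastResult:
    pair: str
    endpoint: str
    horizon_years: float
    subgroup: str
    mean_diff: float
    ci_lo: float
    ci_hi: float
    n: int

    def __post_init__(self):
        if not (self.ci_lo <= self.mean_diff <= self.ci_hi):
            raise SimulationError("confidence interval must contain the mean")


def _covariate_matrix(cohort: Cohort) -> np.ndarray:
    cm = cohort.covariate_matrix()
    return cm[["age", "sex_female", "years_since_diagnosis",
               "cvd_history"]].to_numpy(dtype=float)


def run_cohort(cohort: Cohort, timelines: TimelineSet, equations: EquationSet,
               event_models: Mapping[str, EventModel],
               registry: EffectsRegistry, mode: str = "expected",
               seed: int | None = None,
               arm_label: str | None = None) -> CohortSimulation:
    """Simulate every individual through their timeline (vectorised)."""
    n = len(cohort)
    if len(timelines) != n:
        raise SimulationError("cohort and timelines differ in size")
    ids_c = cohort.frame["id"].to_numpy()
    if not np.array_equal(ids_c.astype(str), timelines.ids.astype(str)):
        raise SimulationError("cohort and timeline ids do not match")
    own = np.array([int(SECOND_LINE_DUAL[c])
                    for c in cohort.frame["second_line_class"]])
    first = timelines.regimens[:, 0].astype(int)
    fu = timelines.follow_up()
    if arm_label is None and np.any((fu > 0) & (first != own)):
        raise SimulationError("quarter-0 regimen must be the metformin dual "
                              "matching each individual's second-line class")

    H = timelines.n_quarters
    missing = set(EVENTS) - set(event_models)
    if missing:
        raise SimulationError(f"missing event model(s): {sorted(missing)}")

    rf_lookup = effect_matrix(registry, RISK_FACTORS)
    ev_lookup = effect_matrix(registry, EVENTS)
    ev_cov = _covariate_matrix(cohort)

    rng = (np.random.default_rng(np.random.SeedSequence([int(seed), 0x51E]))
           if mode == "stochastic" else None)

    X = cohort.risk_factor_matrix().copy()
    factors = np.full((n, H, len(RISK_FACTORS)), np.nan)
    probs = np.full((n, H, len(EVENTS)), np.nan)
    occurrences = (np.zeros((n, H, len(EVENTS)), dtype=bool)
                   if mode == "stochastic" else None)
    counts = np.zeros((n, len(EVENTS)))           # prior-event counts
    alive = np.ones(n, dtype=bool)
    death_quarter = np.full(n, -1, dtype=np.int16)
    base_cov = cohort.covariate_matrix().to_numpy(dtype=float)  # 4 columns

    recurrent_idx = [EVENTS.index(e) for e in RECURRENT_EVENTS]
    death_idx = EVENTS.index("all_cause_death")

    for q in range(H):
        active = (fu > q) & alive
        if not active.any():
            break
        reg = timelines.regimens[:, q].astype(int)
        reg = np.where(reg < 0, 0, reg)  # masked out below
        factors[active, q] = X[active]

        # (2) event probabilities from the current state
        for e, name in enumerate(EVENTS):
            model = event_models[name]
            prior = counts[:, e] if model.recurrent else 0.0
            lp = model.linear_predictor(X, ev_cov, q, prior)
            lp = lp + ev_lookup[reg, e]
            p = expit(lp)
            if model.absorbing:
                p = np.where(counts[:, e] >= 1, np.nan, p)
            probs[active, q, e] = p[active]

        if mode == "stochastic":
            u = rng.random((n, len(EVENTS)))
            occ = (u < np.nan_to_num(probs[:, q, :], nan=-1.0)) \
                & active[:, None]
            occurrences[:, q, :] = occ
            counts += occ
            died = occ[:, death_idx]
            death_quarter[died] = q
            alive &= ~died
        else:
            # expected mode: recurrent prior counts accumulate expected
            # events; absorbing states are not absorbed in expectation (the
            # naive cumulative-incidence convention)
            for e in recurrent_idx:
                counts[active, e] += probs[active, q, e]

        # (3) advance risk factors
        if q < H - 1:
            cov6 = np.column_stack([
                base_cov,
                timelines.statin[:, q].astype(float),
                timelines.bp_lowering[:, q].astype(float),
            ])
            X_new = advance_states(X, cov6, reg, equations, rf_lookup, q,
                                   mode=mode, rng=rng)
            X = np.where(active[:, None], X_new, X)

    label = arm_label or cohort.frame["second_line_class"].to_numpy()
    return CohortSimulation(ids_c, label, factors, probs, fu,
                            timelines.censor_quarter, death_quarter,
                            occurrences)


def _single(profile: BaselineProfile, timeline: PathwayTimeline) -> tuple:
    frame = pd.DataFrame([{
        "id": profile.id, "age": profile.age, "sex": profile.sex,
        "ethnicity": profile.ethnicity, "imd_quintile": profile.imd_quintile,
        "years_since_diagnosis": profile.years_since_diagnosis,
        **{f: getattr(profile.risk_factors, f) for f in RISK_FACTORS},
        **{f"history_{k}": v for k, v in profile.history_flags.items()},
        "cvd_history": profile.cvd_history,
        "second_line_class": profile.second_line_class,
    }])
    return Cohort(frame), TimelineSet.from_timelines([timeline])


def run_individual(profile: BaselineProfile, timeline: PathwayTimeline,
                   equations: EquationSet,
                   event_models: Mapping[str, EventModel],
                   registry: EffectsRegistry, mode: str = "expected",
                   seed: int | None = None) -> SimulationResult:
    """Simulate one individual; quarter-0 regimen must match their class."""
    if timeline.n_quarters:
        expected = SECOND_LINE_DUAL[profile.second_line_class]
        if RegimenCode(int(timeline.regimens[0])) != expected:
            raise SimulationError(
                "timeline quarter 0 must be the metformin dual matching the "
                f"profile's second-line class ({expected.name})")
    cohort, tls = _single(profile, timeline)
    sim = run_cohort(cohort, tls, equations, event_models, registry,
                     mode=mode, seed=seed)
    return sim.individual(0)


def counterfactual_timelines(timelines: TimelineSet, arm: str) -> TimelineSet:
    """Identical copies with the second-line quarters re-labelled to ``arm``'s
    metformin dual; downstream regimens and censoring untouched."""
    target = int(SECOND_LINE_DUAL[arm])
    reg = timelines.regimens.copy()
    own = reg[:, 0][:, None]  # quarter-0 code is the own dual by contract
    on_own = (reg == own) & (reg >= 0)
    reg[on_own] = target
    return TimelineSet(timelines.ids, reg, timelines.statin,
                       timelines.bp_lowering, timelines.censor_quarter,
                       timelines.death_quarter)


def run_counterfactual_cohort(cohort: Cohort, timelines: TimelineSet,
                              equations: EquationSet,
                              event_models: Mapping[str, EventModel],
                              registry: EffectsRegistry,
                              mode: str = "expected", seed: int | None = 7,
                              arms: Sequence[str] = ("SU", "DPP4i", "SGLT2i"),
                              ) -> dict[str, CohortSimulation]:
    """Three counterfactual runs for the whole cohort (common random
    numbers in stochastic mode: every arm uses the identical seed)."""
    out = {}
    for arm in arms:
        tls = counterfactual_timelines(timelines, arm)
        out[arm] = run_cohort(cohort, tls, equations, event_models, registry,
                              mode=mode, seed=seed, arm_label=arm)
    return out


def run_counterfactuals(profile: BaselineProfile, timeline: PathwayTimeline,
                        equations: EquationSet,
                        event_models: Mapping[str, EventModel],
                        registry: EffectsRegistry, mode: str = "expected",
                        seed: int | None = 7) -> dict[str, SimulationResult]:
    """Per-individual counterfactual triple (SU, DPP4i, SGLT2i)."""
    if timeline.n_quarters:
        expected = SECOND_LINE_DUAL[profile.second_line_class]
        if RegimenCode(int(timeline.regimens[0])) != expected:
            raise SimulationError("timeline/profile mismatch at quarter 0")
    cohort, tls = _single(profile, timeline)
    sims = run_counterfactual_cohort(cohort, tls, equations, event_models,
                                     registry, mode=mode, seed=seed)
    return {arm: sim.individual(0) for arm, sim in sims.items()}


# ---------------------------------------------------------------------------
# aggregation & contrasts
# ---------------------------------------------------------------------------

def _endpoint_values(sim: CohortSimulation, endpoint: str,
                     horizon_years: float) -> tuple[np.ndarray, np.ndarray]:
    """(values, contributes) for one endpoint at a horizon.

    Endpoints: ``"cum_inc:<event>"``, ``"count:<event>"``,
    ``"level:<factor>"``.  Contribution requires follow-up >= the horizon
    (>= horizon quarter + 1 for levels, whose state is read at that quarter).
    """
    hq = int(round(4 * horizon_years))
    kind, _, name = endpoint.partition(":")
    if kind == "cum_inc":
        values = sim.cumulative_incidence(name, hq)
        mask = sim.follow_up >= hq
    elif kind == "count":
        values = sim.expected_count(name, hq)
        mask = sim.follow_up >= hq
    elif kind == "level":
        values = sim.level(name, hq)
        mask = sim.follow_up >= hq + 1
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return values, mask


def aggregate(sim: CohortSimulation, endpoint: str,
              horizon_years: float) -> dict:
    """Mean and normal-based 95% CI across contributing individuals."""
    values, mask = _endpoint_values(sim, endpoint, horizon_years)
    v = values[mask]
    n = int(mask.sum())
    if n < 2:
        raise SimulationError(
            f"need >= 2 individuals with follow-up at {horizon_years}y "
            f"(have {n})")
    mean = float(np.mean(v))
    half = Z95 * float(np.std(v, ddof=1)) / np.sqrt(n)
    return {"mean": mean, "ci_lo": mean - half, "ci_hi": mean + half, "n": n}


def _subgroup_mask(cohort: Cohort, subgroup: str) -> np.ndarray:
    cvd = cohort.frame["cvd_history"].to_numpy(dtype=bool)
    if subgroup == "overall":
        return np.ones(len(cohort), dtype=bool)
    if subgroup == "CVD":
        return cvd
    if subgroup == "no-CVD":
        return ~cvd
    raise ValueError(f"unknown subgroup {subgroup!r}")


def contrast(results_by_arm: Mapping[str, CohortSimulation],
             pair: tuple[str, str], endpoint: str, horizon_years: float,
             subgroup: str = "overall",
             cohort: Cohort | None = None) -> ContrastResult:
    """Paired within-individual difference arm_a - arm_b, aggregated with a
    normal-based 95% CI.  Both arms must cover the same individuals."""
    a, b = pair
    sim_a, sim_b = results_by_arm[a], results_by_arm[b]
    if not np.array_equal(sim_a.ids, sim_b.ids):
        raise SimulationError("contrast requires identical individuals in "
                              "both arms (pairing is mandatory)")
    va, ma = _endpoint_values(sim_a, endpoint, horizon_years)
    vb, mb = _endpoint_values(sim_b, endpoint, horizon_years)
    mask = ma & mb
    if subgroup != "overall":
        if cohort is None:
            raise ValueError("subgroup contrasts need the cohort")
        mask &= _subgroup_mask(cohort, subgroup)
    n = int(mask.sum())
    if n < 2:
        raise SimulationError(f"need >= 2 paired individuals (have {n})")
    d = va[mask] - vb[mask]
    mean = float(np.mean(d))
    half = Z95 * float(np.std(d, ddof=1)) / np.sqrt(n)
    return ContrastResult(pair=f"{a}-{b}", endpoint=endpoint,
                          horizon_years=horizon_years, subgroup=subgroup,
                          mean_diff=mean, ci_lo=mean - half,
                          ci_hi=mean + half, n=n)


def contrast_table(results_by_arm: Mapping[str, CohortSimulation],
                   endpoints: Sequence[str],
                   horizons_years: Sequence[float] = (5.0,),
                   subgroups: Sequence[str] = ("overall", "CVD", "no-CVD"),
                   cohort: Cohort | None = None,
                   pairs=CONTRAST_PAIRS) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        for endpoint in endpoints:
            for h in horizons_years:
                for sg in subgroups:
                    c = contrast(results_by_arm, pair, endpoint, h, sg, cohort)
                    rows.append({"pair": c.pair, "endpoint": c.endpoint,
                                 "horizon_years": c.horizon_years,
                                 "subgroup": c.subgroup,
                                 "mean_diff": c.mean_diff,
                                 "ci_lo": c.ci_lo, "ci_hi": c.ci_hi,
                                 "n": c.n})
    return pd.DataFrame(rows)
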