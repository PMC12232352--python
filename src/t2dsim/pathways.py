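"""Quarter-resolution treatment-pathway simulation.

Each individual starts on their metformin dual therapy (second line) and
evolves through a first-order Markov chain over regimen *categories* in
90-day quarters, with administrative censoring drawn independently of the
regimen.  The default transition spec is calibrated by deterministic
moment-matching of the chain's exact marginal distribution to published
pathway statistics: 73.5% own-dual persistence among those under follow-up
at one year (equivalently 33/28/7% of the full cohort on metformin-SU /
-DPP4i / -SGLT2i), metformin monotherapy 12% and triple therapy 7% of the
cohort at one year, 31% triple-or-other among those still followed at the
end of the 7.6-year horizon, and the published available-follow-up counts
(84% censored by year 7).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort
from .errors import ConfigurationError

__all__ = [
    "HORIZON_QUARTERS",
    "RegimenCode",
    "PathwayState",
    "PathwayTimeline",
    "TimelineSet",
    "TransitionSpec",
    "simulate_pathways",
    "pathway_prevalence",
    "censoring_curve",
    "default_transition_spec",
]

#: Maximum simulation horizon: 7.6 years at 90-day quarters.
HORIZON_QUARTERS = 31


class RegimenCode(IntEnum):
    """Drug-class combination categories for glucose-lowering therapy."""

    NO_THERAPY = 0
    MET_MONO = 1
    SU_MONO = 2
    DPP4I_MONO = 3
    SGLT2I_MONO = 4
    GLP1RA_MONO = 5
    TZD_MONO = 6
    INSULIN_MONO = 7
    MET_SU = 8
    MET_DPP4I = 9
    MET_SGLT2I = 10
    MET_GLP1RA = 11
    MET_TZD = 12
    MET_INSULIN = 13
    SU_TZD = 14
    SU_INSULIN = 15
    TZD_INSULIN = 16
    TRIPLE_OR_OTHER = 17


#: Component drug classes per regimen code.  TRIPLE_OR_OTHER is resolved at
#: effect-lookup time via the registry's configured representative
#: composition, hence None here.
REGIMEN_COMPONENTS: dict[RegimenCode, tuple[str, ...] | None] = {
    RegimenCode.NO_THERAPY: (),
    RegimenCode.MET_MONO: ("metformin",),
    RegimenCode.SU_MONO: ("SU",),
    RegimenCode.DPP4I_MONO: ("DPP4i",),
    RegimenCode.SGLT2I_MONO: ("SGLT2i",),
    RegimenCode.GLP1RA_MONO: ("GLP1RA",),
    RegimenCode.TZD_MONO: ("TZD",),
    RegimenCode.INSULIN_MONO: ("insulin",),
    RegimenCode.MET_SU: ("metformin", "SU"),
    RegimenCode.MET_DPP4I: ("metformin", "DPP4i"),
    RegimenCode.MET_SGLT2I: ("metformin", "SGLT2i"),
    RegimenCode.MET_GLP1RA: ("metformin", "GLP1RA"),
    RegimenCode.MET_TZD: ("metformin", "TZD"),
    RegimenCode.MET_INSULIN: ("metformin", "insulin"),
    RegimenCode.SU_TZD: ("SU", "TZD"),
    RegimenCode.SU_INSULIN: ("SU", "insulin"),
    RegimenCode.TZD_INSULIN: ("TZD", "insulin"),
    RegimenCode.TRIPLE_OR_OTHER: None,
}

SECOND_LINE_DUAL = {
    "SU": RegimenCode.MET_SU,
    "DPP4i": RegimenCode.MET_DPP4I,
    "SGLT2i": RegimenCode.MET_SGLT2I,
}


class PathwayState(IntEnum):
    """Category-level Markov states; OWN_DUAL is the individual's initial
    metformin dual and is never re-entered once left."""

    OWN_DUAL = 0
    MET_MONO = 1
    OTHER_MONO = 2
    OTHER_DUAL = 3
    TRIPLE = 4
    NO_THERAPY = 5


_NON_OWN = [PathwayState.MET_MONO, PathwayState.OTHER_MONO,
            PathwayState.OTHER_DUAL, PathwayState.TRIPLE,
            PathwayState.NO_THERAPY]


@dataclass
class PathwayTimeline:
    """One individual's per-quarter regimen and concomitant-therapy flags."""

    id: str
    regimens: np.ndarray          # RegimenCode values, length = observed quarters
    statin: np.ndarray            # bool, same length
    bp_lowering: np.ndarray       # bool, same length
    censor_quarter: int | None    # first unobserved quarter, None if full horizon
    death_quarter: int | None = None

    def __post_init__(self):
        T = len(self.regimens)
        if T > HORIZON_QUARTERS:
            raise ConfigurationError("timeline exceeds the 31-quarter horizon")
        if self.censor_quarter is not None and T > self.censor_quarter:
            raise ConfigurationError("entries at/after the censoring quarter")

    @property
    def n_quarters(self) -> int:
        return len(self.regimens)


class TimelineSet:
    """Columnar container of all timelines (regimens: (n, 31) int8 with -1
    after censoring; censor_quarter: -1 encodes 'never censored')."""

    def __init__(self, ids: np.ndarray, regimens: np.ndarray,
                 statin: np.ndarray, bp_lowering: np.ndarray,
                 censor_quarter: np.ndarray,
                 death_quarter: np.ndarray | None = None):
        self.ids = np.asarray(ids)
        self.regimens = np.asarray(regimens, dtype=np.int8)
        self.statin = np.asarray(statin, dtype=bool)
        self.bp_lowering = np.asarray(bp_lowering, dtype=bool)
        self.censor_quarter = np.asarray(censor_quarter, dtype=np.int16)
        self.death_quarter = (np.full(len(self.ids), -1, dtype=np.int16)
                              if death_quarter is None
                              else np.asarray(death_quarter, dtype=np.int16))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_quarters(self) -> int:
        return self.regimens.shape[1]

    def follow_up(self) -> np.ndarray:
        """Observed quarters per individual (censor quarter, or the horizon)."""
        fu = self.censor_quarter.astype(np.int32).copy()
        fu[fu < 0] = self.n_quarters
        return fu

    def at_risk(self, quarter: int) -> np.ndarray:
        """Uncensored (and not dead) at the given quarter."""
        ok = self.follow_up() > quarter
        if self.death_quarter is not None:
            dead = (self.death_quarter >= 0) & (self.death_quarter <= quarter)
            ok &= ~dead
        return ok

    def __iter__(self) -> Iterator[PathwayTimeline]:
        fu = self.follow_up()
        for i in range(len(self)):
            T = int(fu[i])
            cq = int(self.censor_quarter[i])
            dq = int(self.death_quarter[i])
            yield PathwayTimeline(
                id=str(self.ids[i]),
                regimens=self.regimens[i, :T].copy(),
                statin=self.statin[i, :T].copy(),
                bp_lowering=self.bp_lowering[i, :T].copy(),
                censor_quarter=None if cq < 0 else cq,
                death_quarter=None if dq < 0 else dq,
            )

    @classmethod
    def from_timelines(cls, timelines: Sequence[PathwayTimeline],
                       n_quarters: int = HORIZON_QUARTERS) -> "TimelineSet":
        n = len(timelines)
        reg = np.full((n, n_quarters), -1, dtype=np.int8)
        st = np.zeros((n, n_quarters), dtype=bool)
        bp = np.zeros((n, n_quarters), dtype=bool)
        cq = np.full(n, -1, dtype=np.int16)
        dq = np.full(n, -1, dtype=np.int16)
        ids = []
        for i, tl in enumerate(timelines):
            T = tl.n_quarters
            reg[i, :T] = tl.regimens
            st[i, :T] = tl.statin
            bp[i, :T] = tl.bp_lowering
            if tl.censor_quarter is not None:
                cq[i] = tl.censor_quarter
            elif T < n_quarters:
                cq[i] = T  # a short timeline ends observation at its end
            if tl.death_quarter is not None:
                dq[i] = tl.death_quarter
            ids.append(tl.id)
        return cls(np.array(ids, dtype=object), reg, st, bp, cq, dq)

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialisation (id, quarter, regimen, statin,
        bp_lowering); censored quarters are omitted."""
        fu = self.follow_up()
        rows = np.repeat(np.arange(len(self)), fu)
        quarters = np.concatenate([np.arange(T) for T in fu]) if len(fu) else []
        return pd.DataFrame({
            "id": self.ids[rows],
            "quarter": quarters,
            "regimen": [RegimenCode(r).name
                        for r in self.regimens[rows, quarters]],
            "statin": self.statin[rows, quarters],
            "bp_lowering": self.bp_lowering[rows, quarters],
        })


@dataclass
class TransitionSpec:
    """Hazards and destination distributions of the category-level chain.

    ``year_band(q)`` maps a quarter to a band index; leave hazards and
    leave-destination distributions may differ by band.  ``switch`` holds the
    per-quarter transition rows of the non-own states (probability of moving
    to each other non-own state; the remainder is the stay probability).
    ``censor_hazard[q]`` is the probability of being censored at quarter q
    given follow-up through q-1 (index 0 unused).
    """

    band_starts: tuple[int, ...]                       # e.g. (0, 4, 12)
    leave_hazard: tuple[float, ...]                    # per band
    leave_destinations: tuple[Mapping[PathwayState, float], ...]
    switch: Mapping[PathwayState, Mapping[PathwayState, float]]
    censor_hazard: np.ndarray                          # length HORIZON_QUARTERS
    statin_prevalence: float = 0.75
    bp_lowering_prevalence: float = 0.65
    other_dual_dist: Mapping[RegimenCode, float] = field(default_factory=dict)
    other_mono_dist: Mapping[RegimenCode, float] = field(default_factory=dict)

    def __post_init__(self):
        self.censor_hazard = np.asarray(self.censor_hazard, dtype=float)

    def validate(self) -> None:
        if len(self.leave_hazard) != len(self.band_starts) or \
                len(self.leave_destinations) != len(self.band_starts):
            raise ConfigurationError("one leave hazard and destination "
                                     "distribution required per year band")
        for h in self.leave_hazard:
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"leave hazard {h} outside [0, 1]")
        for dist in self.leave_destinations:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"destination distribution sums to {total}, not 1")
        for state, row in self.switch.items():
            if PathwayState.OWN_DUAL in row:
                raise ConfigurationError("re-entry into the own second-line "
                                         "dual is not modelled")
            total = sum(row.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in row.values()):
                raise ConfigurationError(
                    f"switch row for {state.name} is not a sub-distribution")
        if np.any((self.censor_hazard < 0) | (self.censor_hazard > 1)):
            raise ConfigurationError("censoring hazards must lie in [0, 1]")
        for name, dist in [("other_dual_dist", self.other_dual_dist),
                           ("other_mono_dist", self.other_mono_dist)]:
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")

    def band(self, quarter: int) -> int:
        b = 0
        for i, start in enumerate(self.band_starts):
            if quarter >= start:
                b = i
        return b

    # -- deterministic marginals (used for moment-matching and tests) -------
    def transition_matrix(self, quarter: int) -> np.ndarray:
        """6x6 row-stochastic matrix of the category chain at this quarter."""
        P = np.zeros((6, 6))
        b = self.band(quarter)
        l = self.leave_hazard[b]
        P[PathwayState.OWN_DUAL, PathwayState.OWN_DUAL] = 1.0 - l
        for state, p in self.leave_destinations[b].items():
            P[PathwayState.OWN_DUAL, state] += l * p
        for state in _NON_OWN:
            row = self.switch.get(state, {})
            out = 0.0
            for dest, p in row.items():
                P[state, dest] += p
                out += p
            P[state, state] += 1.0 - out
        return P

    def marginal_state_distribution(
            self, horizon: int = HORIZON_QUARTERS) -> np.ndarray:
        """Exact state marginals (horizon, 6): everyone starts in OWN_DUAL.
        Censoring is independent of state so marginals among those at risk
        equal the chain's unconditional marginals."""
        dist = np.zeros((horizon, 6))
        dist[0, PathwayState.OWN_DUAL] = 1.0
        for q in range(1, horizon):
            dist[q] = dist[q - 1] @ self.transition_matrix(q)
        return dist

    def censoring_survival(self) -> np.ndarray:
        """P(follow-up > q) for q = 0..horizon-1."""
        return np.cumprod(1.0 - self.censor_hazard)

    def to_dict(self) -> dict:
        return {
            "band_starts": list(self.band_starts),
            "leave_hazard": list(map(float, self.leave_hazard)),
            "leave_destinations": [
                {PathwayState(k).name: float(v) for k, v in d.items()}
                for d in self.leave_destinations],
            "switch": {PathwayState(s).name:
                       {PathwayState(d).name: float(p) for d, p in row.items()}
                       for s, row in self.switch.items()},
            "censor_hazard": [float(h) for h in self.censor_hazard],
            "statin_prevalence": self.statin_prevalence,
            "bp_lowering_prevalence": self.bp_lowering_prevalence,
            "other_dual_dist": {RegimenCode(k).name: float(v)
                                for k, v in self.other_dual_dist.items()},
            "other_mono_dist": {RegimenCode(k).name: float(v)
                                for k, v in self.other_mono_dist.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionSpec":
        return cls(
            band_starts=tuple(d["band_starts"]),
            leave_hazard=tuple(d["leave_hazard"]),
            leave_destinations=tuple(
                {PathwayState[k]: v for k, v in dist.items()}
                for dist in d["leave_destinations"]),
            switch={PathwayState[s]: {PathwayState[t]: p
                                      for t, p in row.items()}
                    for s, row in d["switch"].items()},
            censor_hazard=np.asarray(d["censor_hazard"], dtype=float),
            statin_prevalence=d.get("statin_prevalence", 0.75),
            bp_lowering_prevalence=d.get("bp_lowering_prevalence", 0.65),
            other_dual_dist={RegimenCode[k]: v
                             for k, v in d.get("other_dual_dist", {}).items()},
            other_mono_dist={RegimenCode[k]: v
                             for k, v in d.get("other_mono_dist", {}).items()},
        )


# ---------------------------------------------------------------------------
# default calibrated spec
# ---------------------------------------------------------------------------

#: Published available-follow-up counts at years 0..7 (full cohort 62,640).
AVAILABLE_FOLLOW_UP = (62_640, 57_951, 46_726, 36_814, 28_170,
                       20_917, 14_988, 10_035)

# Moment targets (see module docstring; "at-risk" = among uncensored).
_TARGET_OWN_DUAL_Q4 = 0.735      # at-risk own-dual persistence at one year
_TARGET_OWN_DUAL_END = 0.32      # 16% + 12% + 4% of at-risk at end of follow-up
_TARGET_MET_MONO_Y1 = 0.12       # of full cohort at one year
_TARGET_TRIPLE_Y1 = 0.07         # of full cohort at one year
_TARGET_TRIPLE_END = 0.31        # of at-risk at end of follow-up


def censoring_hazards_from_counts(
        counts: Sequence[int] = AVAILABLE_FOLLOW_UP) -> np.ndarray:
    """Per-quarter censoring hazards with a constant hazard within each year,
    matched exactly to yearly available-follow-up counts (extended at the
    final year's hazard beyond the last printed year)."""
    counts = np.asarray(counts, dtype=float)
    surv = counts / counts[0]
    h = np.zeros(HORIZON_QUARTERS)
    for year in range(1, len(counts)):
        ratio = surv[year] / surv[year - 1]
        hq = 1.0 - ratio ** 0.25
        h[4 * (year - 1) + 1: 4 * year + 1] = hq
    h[4 * (len(counts) - 1) + 1:] = h[4 * (len(counts) - 1)]
    return h


def _build_spec(l1, l2, d1_mm, d1_tr, d2_tr,
                censor_hazard) -> TransitionSpec:
    d1_rest = 1.0 - d1_mm - d1_tr
    # remaining year-1 destination mass split: other dual 35%, other mono 20%,
    # no therapy 45% of the remainder (treatment breaks are common early)
    d1 = {PathwayState.MET_MONO: d1_mm, PathwayState.TRIPLE: d1_tr,
          PathwayState.OTHER_DUAL: 0.35 * d1_rest,
          PathwayState.OTHER_MONO: 0.20 * d1_rest,
          PathwayState.NO_THERAPY: 0.45 * d1_rest}
    d2_rest = 1.0 - 0.15 - d2_tr - 0.15 - 0.05
    d2 = {PathwayState.MET_MONO: 0.15, PathwayState.TRIPLE: d2_tr,
          PathwayState.OTHER_DUAL: 0.15, PathwayState.OTHER_MONO: 0.05,
          PathwayState.NO_THERAPY: d2_rest}
    switch = {
        PathwayState.MET_MONO: {PathwayState.TRIPLE: 0.010,
                                PathwayState.OTHER_DUAL: 0.010,
                                PathwayState.NO_THERAPY: 0.005},
        PathwayState.OTHER_MONO: {PathwayState.TRIPLE: 0.020},
        PathwayState.OTHER_DUAL: {PathwayState.TRIPLE: 0.020},
        PathwayState.NO_THERAPY: {PathwayState.MET_MONO: 0.050},
        PathwayState.TRIPLE: {},
    }
    return TransitionSpec(
        band_starts=(0, 5, 13),
        leave_hazard=(l1, l2, l2),
        leave_destinations=(d1, d2, d2),
        switch=switch,
        censor_hazard=censor_hazard,
        other_dual_dist={
            RegimenCode.MET_INSULIN: 0.40, RegimenCode.MET_TZD: 0.10,
            RegimenCode.MET_GLP1RA: 0.15, RegimenCode.SU_INSULIN: 0.10,
            RegimenCode.MET_SU: 0.10, RegimenCode.MET_DPP4I: 0.10,
            RegimenCode.MET_SGLT2I: 0.05},
        other_mono_dist={
            RegimenCode.SU_MONO: 0.25, RegimenCode.DPP4I_MONO: 0.20,
            RegimenCode.INSULIN_MONO: 0.30, RegimenCode.GLP1RA_MONO: 0.15,
            RegimenCode.SGLT2I_MONO: 0.05, RegimenCode.TZD_MONO: 0.05},
    )


def calibrate_transition_spec() -> TransitionSpec:
    """Deterministic moment-matching of the default transition spec.

    Solved quantities: the year-1 leave hazard (own-dual persistence 0.735 at
    quarter 4), the later leave hazard (0.32 at quarter 30), the year-1
    destination masses to metformin-mono and triple (cohort shares 12% and 7%
    at year 1 after accounting for within-year onward movement and
    censoring), and the later destination mass to triple (31% at-risk triple
    at quarter 30).  All moments are evaluated on the chain's exact marginal
    distribution; no simulation is involved.
    """
    censor = censoring_hazards_from_counts()
    cens_surv = np.cumprod(1.0 - censor)
    l1 = 1.0 - _TARGET_OWN_DUAL_Q4 ** 0.25
    l2 = 1.0 - (_TARGET_OWN_DUAL_END / _TARGET_OWN_DUAL_Q4) ** (1.0 / 26.0)

    def q4_moments(d1_mm, d1_tr, d2_tr=0.45):
        spec = _build_spec(l1, l2, d1_mm, d1_tr, d2_tr, censor)
        dist = spec.marginal_state_distribution()
        mm_cohort = dist[4, PathwayState.MET_MONO] * cens_surv[4]
        tr_cohort = dist[4, PathwayState.TRIPLE] * cens_surv[4]
        return mm_cohort, tr_cohort, dist

    def resid(x):
        mm, tr, _ = q4_moments(x[0], x[1])
        return [mm - _TARGET_MET_MONO_Y1, tr - _TARGET_TRIPLE_Y1]

    sol = optimize.root(resid, x0=[0.49, 0.28], tol=1e-12)
    if not sol.success:  # pragma: no cover
        raise RuntimeError("year-1 destination calibration failed")
    d1_mm, d1_tr = sol.x

    def triple_end(d2_tr):
        spec = _build_spec(l1, l2, d1_mm, d1_tr, d2_tr, censor)
        dist = spec.marginal_state_distribution()
        return dist[HORIZON_QUARTERS - 1, PathwayState.TRIPLE] - _TARGET_TRIPLE_END

    d2_tr = optimize.brentq(triple_end, 0.01, 0.60, xtol=1e-12)
    spec = _build_spec(l1, l2, d1_mm, d1_tr, d2_tr, censor)
    spec.validate()
    return spec


@functools.lru_cache(maxsize=1)
def default_transition_spec() -> TransitionSpec:
    return calibrate_transition_spec()


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _dist_arrays(dist: Mapping, dtype=np.int8):
    codes = np.array([int(k) for k in dist.keys()], dtype=dtype)
    probs = np.array([float(v) for v in dist.values()])
    return codes, probs / probs.sum()


def simulate_pathways(cohort: Cohort, spec: TransitionSpec, seed: int,
                      horizon: int = HORIZON_QUARTERS) -> TimelineSet:
    """Simulate one timeline per individual.

    Quarter 0 is the individual's metformin dual matching their assigned
    second-line class.  At each subsequent quarter the censoring hazard is
    applied first (independently of regimen), then the category chain steps;
    on entry into OTHER_MONO / OTHER_DUAL a concrete regimen code is sampled
    (sticky while the category is held; the own dual is excluded and the
    residual distribution renormalised).  Statin and blood-pressure-therapy
    flags are independent per-quarter Bernoulli draws at the configured
    prevalences.  Fully deterministic for fixed (cohort, spec, seed).
    """
    spec.validate()
    n = len(cohort)
    if n == 0:
        raise ConfigurationError("cohort must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A7]))

    own_dual = np.array([int(SECOND_LINE_DUAL[c]) for c in
                         cohort.frame["second_line_class"]], dtype=np.int8)
    states = np.full(n, int(PathwayState.OWN_DUAL), dtype=np.int8)
    regimens = np.full((n, horizon), -1, dtype=np.int8)
    regimens[:, 0] = own_dual
    censor_q = np.full(n, -1, dtype=np.int16)
    observed = np.ones(n, dtype=bool)
    sticky = np.full(n, -1, dtype=np.int8)  # concrete code while in OTHER_*

    od_codes, od_probs = _dist_arrays(spec.other_dual_dist)
    om_codes, om_probs = _dist_arrays(spec.other_mono_dist)

    state_to_code = {
        int(PathwayState.MET_MONO): int(RegimenCode.MET_MONO),
        int(PathwayState.TRIPLE): int(RegimenCode.TRIPLE_OR_OTHER),
        int(PathwayState.NO_THERAPY): int(RegimenCode.NO_THERAPY),
    }

    def sample_concrete(idx, codes, probs):
        """Sample sticky codes for idx, excluding each individual's own dual."""
        u = rng.random(len(idx))
        out = np.empty(len(idx), dtype=np.int8)
        for j, i in enumerate(idx):
            mask = codes != own_dual[i]
            p = probs[mask]
            p = p / p.sum()
            out[j] = codes[mask][np.searchsorted(np.cumsum(p), u[j],
                                                 side="right").clip(0, len(p) - 1)]
        return out

    for q in range(1, horizon):
        # censoring (independent of regimen)
        h = spec.censor_hazard[q]
        newly = observed & (rng.random(n) < h)
        censor_q[newly] = q
        observed &= ~newly

        # chain step for everyone (censoring independence means we may evolve
        # all individuals; censored entries are masked out afterwards)
        P = spec.transition_matrix(q)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        new_states = np.empty(n, dtype=np.int8)
        for s in range(6):
            mask = states == s
            if not mask.any():
                continue
            new_states[mask] = np.searchsorted(cum[s], u[mask], side="right")
        entered = new_states != states
        for st, codes, probs in [(PathwayState.OTHER_DUAL, od_codes, od_probs),
                                 (PathwayState.OTHER_MONO, om_codes, om_probs)]:
            idx = np.nonzero(entered & (new_states == int(st)))[0]
            if len(idx):
                sticky[idx] = sample_concrete(idx, codes, probs)
        states = new_states

        code = np.where(states == int(PathwayState.OWN_DUAL), own_dual, 0)
        for s, c in state_to_code.items():
            code = np.where(states == s, c, code)
        in_other = np.isin(states, [int(PathwayState.OTHER_DUAL),
                                    int(PathwayState.OTHER_MONO)])
        code = np.where(in_other, sticky, code)
        regimens[observed, q] = code[observed]

    statin = rng.random((n, horizon)) < spec.statin_prevalence
    bp = rng.random((n, horizon)) < spec.bp_lowering_prevalence
    fu = censor_q.astype(np.int32).copy()
    fu[fu < 0] = horizon
    col = np.arange(horizon)[None, :]
    unobserved = col >= fu[:, None]
    statin[unobserved] = False
    bp[unobserved] = False
    regimens[unobserved] = -1

    return TimelineSet(cohort.frame["id"].to_numpy(), regimens, statin, bp,
                       censor_q)


def pathway_prevalence(timelines: TimelineSet, quarter: int,
                       denominator: str = "at_risk") -> pd.Series:
    """Regimen-category distribution at a quarter.

    ``denominator="at_risk"`` (default): proportions among uncensored-and-
    alive individuals, summing to 1; ``denominator="cohort"``: proportions of
    the full baseline cohort (summing to the at-risk fraction).  The count of
    at-risk individuals is attached as ``.attrs["n_at_risk"]``.
    """
    if not 0 <= quarter < timelines.n_quarters:
        raise ValueError(f"quarter {quarter} outside the simulated horizon")
    at_risk = timelines.at_risk(quarter)
    n_risk = int(at_risk.sum())
    if n_risk == 0:
        raise ValueError("no uncensored individuals at this quarter (n=0)")
    codes = timelines.regimens[at_risk, quarter]
    denom = n_risk if denominator == "at_risk" else len(timelines)
    counts = np.bincount(codes, minlength=len(RegimenCode))
    out = pd.Series(counts / denom,
                    index=[c.name for c in RegimenCode], dtype=float)
    out.attrs["n_at_risk"] = n_risk
    out.attrs["denominator"] = denominator
    return out


def censoring_curve(timelines: TimelineSet) -> pd.Series:
    """Cumulative proportion censored by the end of each year (year 0 = 0).

    "Censored by year y" means a censoring quarter <= 4y, matching the
    convention that available follow-up at year y counts individuals with
    follow-up strictly beyond quarter 4y.
    """
    if len(timelines) == 0:
        raise ValueError("empty timeline collection")
    years = timelines.n_quarters // 4
    cq = timelines.censor_quarter
    out = {}
    for y in range(years + 1):
        out[y] = float(np.mean((cq >= 0) & (cq <= 4 * y)))
    return pd.Series(out, name="cumulative_censored")


def second_line_persistence(timelines: TimelineSet, quarter: int) -> float:
    """Fraction of at-risk individuals still on their original metformin dual
    (quarter-0 regimen) at the given quarter."""
    at_risk = timelines.at_risk(quarter)
    if not at_risk.any():
        raise ValueError("no uncensored individuals at this quarter (n=0)")
    return float(np.mean(timelines.regimens[at_risk, quarter]
                         == timelines.regimens[at_risk, 0]))
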