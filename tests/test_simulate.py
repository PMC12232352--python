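"""Microsimulation core and counterfactual contrasts."""

import numpy as np
import pytest

from t2dsim.cohort import RISK_FACTORS
from t2dsim.effects import (EVENTS, EffectEstimate, EffectsRegistry,
                            default_effects_registry)
from t2dsim.errors import SimulationError
from t2dsim.events import EventModel, default_event_models
from t2dsim.pathways import RegimenCode, default_transition_spec, \
    simulate_pathways
from t2dsim.risk import EquationSet, RiskEquation, default_risk_equations
from t2dsim.simulate import (CohortSimulation, aggregate, contrast,
                             contrast_table, run_cohort,
                             run_counterfactual_cohort, run_counterfactuals,
                             run_individual)
from tests.conftest import make_profile, make_timeline


def identity_equations():
    return EquationSet({f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS})


def intercept_only_models(intercept=-6.0):
    return {name: EventModel(name, intercept=intercept) for name in EVENTS}


def zero_registry():
    return EffectsRegistry([], warn_missing=False)


# -- run_individual ---------------------------------------------------------

def test_three_quarter_worked_example_matches_hand_recursion():
    """Hand-computed forward recursion, frozen:

    hba1c: x[t+1] = 0.8 + 0.9 x[t] - 0.2 (met-SU shift -0.1 per class)
      x = 8.0, 7.8, 7.62
    eye disease: p[t] = expit(-4 + 0.2 * hba1c[t])
      p = expit(-2.4), expit(-2.44), expit(-2.476)
    cumulative incidence = 1 - (1-p0)(1-p1)(1-p2)
    """
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["hba1c"] = RiskEquation("hba1c", intercept=0.8, lag1=0.9)
    registry = EffectsRegistry(
        [EffectEstimate("metformin", "hba1c", "risk_factor_shift", -0.1),
         EffectEstimate("SU", "hba1c", "risk_factor_shift", -0.1)],
        warn_missing=False)
    models = intercept_only_models(-50.0)
    models["eye_disease"] = EventModel("eye_disease", intercept=-4.0,
                                       factor_coefs={"hba1c": 0.2})
    result = run_individual(make_profile(), make_timeline(3),
                            EquationSet(eqs), models, registry)
    hba1c = result.factors[:, RISK_FACTORS.index("hba1c")]
    assert np.allclose(hba1c, [8.0, 7.8, 7.62], atol=1e-12)
    p = result.event_probs[:, EVENTS.index("eye_disease")]
    assert np.allclose(p, [0.08317269649392238, 0.08017291217281233,
                           0.07755788966363435], atol=1e-12)
    assert result.cumulative_incidence("eye_disease") == pytest.approx(
        0.2220837316549369, abs=1e-12)
    assert result.expected_count("eye_disease") == pytest.approx(
        0.24090349833036906, abs=1e-12)


def test_zero_horizon_gives_empty_trajectories():
    result = run_individual(make_profile(),
                            make_timeline(0, censor_quarter=0),
                            identity_equations(), intercept_only_models(),
                            zero_registry())
    assert result.n_quarters == 0
    assert result.cumulative_incidence("mi") == 0.0
    assert result.expected_count("mi") == 0.0


def test_timeline_profile_mismatch_rejected():
    with pytest.raises(SimulationError):
        run_individual(make_profile(second_line_class="DPP4i"),
                       make_timeline(3, RegimenCode.MET_SU),
                       identity_equations(), intercept_only_models(),
                       zero_registry())


def test_arm_blindness_under_null_effects(small_cohort):
    """Zero-effect registry + intercept-only event models: identical event
    probabilities regardless of assigned arm."""
    tl = simulate_pathways(small_cohort, default_transition_spec(), seed=4)
    sims = run_counterfactual_cohort(small_cohort, tl, identity_equations(),
                                     intercept_only_models(), zero_registry())
    a, b, c = (sims[k].event_probs for k in ("SU", "DPP4i", "SGLT2i"))
    assert np.array_equal(a, b, equal_nan=True)
    assert np.array_equal(a, c, equal_nan=True)


# -- counterfactuals --------------------------------------------------------

def test_identical_class_effects_give_bit_identical_counterfactuals():
    shift = [EffectEstimate(cls, "hba1c", "risk_factor_shift", -0.3)
             for cls in ("SU", "DPP4i", "SGLT2i")]
    registry = EffectsRegistry(shift, warn_missing=False)
    results = run_counterfactuals(make_profile(), make_timeline(12),
                                  identity_equations(),
                                  intercept_only_models(), registry)
    su, dpp4i, sglt2i = (results[k] for k in ("SU", "DPP4i", "SGLT2i"))
    assert np.array_equal(su.factors, dpp4i.factors)
    assert np.array_equal(su.factors, sglt2i.factors)
    assert np.array_equal(su.event_probs, sglt2i.event_probs)


def test_stronger_hba1c_effect_dominates_at_every_quarter():
    registry = EffectsRegistry(
        [EffectEstimate("SGLT2i", "hba1c", "risk_factor_shift", -0.5),
         EffectEstimate("DPP4i", "hba1c", "risk_factor_shift", -0.2)],
        warn_missing=False)
    results = run_counterfactuals(make_profile(), make_timeline(12),
                                  identity_equations(),
                                  intercept_only_models(), registry)
    h = RISK_FACTORS.index("hba1c")
    assert (results["SGLT2i"].factors[1:, h]
            < results["DPP4i"].factors[1:, h]).all()


def test_counterfactual_label_swap_antisymmetry(small_cohort, engines):
    equations, models, registry = engines
    tl = simulate_pathways(small_cohort, default_transition_spec(), seed=8)
    sims = run_counterfactual_cohort(small_cohort, tl, equations, models,
                                     registry)
    ab = contrast(sims, ("SGLT2i", "SU"), "cum_inc:eskd", 3.0)
    ba = contrast(sims, ("SU", "SGLT2i"), "cum_inc:eskd", 3.0)
    assert ab.mean_diff == pytest.approx(-ba.mean_diff, abs=1e-15)
    assert ab.ci_lo == pytest.approx(-ba.ci_hi, abs=1e-12)
    assert ab.n == ba.n


def test_counterfactual_only_rewrites_second_line_quarters():
    from t2dsim.pathways import TimelineSet
    from t2dsim.simulate import counterfactual_timelines
    tl = make_timeline(8, RegimenCode.MET_SU)
    tl.regimens[4:] = int(RegimenCode.TRIPLE_OR_OTHER)
    tls = TimelineSet.from_timelines([tl])
    cf = counterfactual_timelines(tls, "SGLT2i")
    assert (cf.regimens[0, :4] == int(RegimenCode.MET_SGLT2I)).all()
    assert (cf.regimens[0, 4:8] == int(RegimenCode.TRIPLE_OR_OTHER)).all()
    assert np.array_equal(cf.censor_quarter, tls.censor_quarter)


# -- aggregation ------------------------------------------------------------

def _fake_sim(values, follow_up=None, ids=None):
    n = len(values)
    factors = np.full((n, 31, len(RISK_FACTORS)), np.nan)
    probs = np.zeros((n, 31, len(EVENTS)))
    probs[:, 0, EVENTS.index("mi")] = values
    fu = np.full(n, 31) if follow_up is None else np.asarray(follow_up)
    return CohortSimulation(
        ids=np.array([f"i{k}" for k in range(n)]) if ids is None else ids,
        arm_label="SU", factors=factors, event_probs=probs, follow_up=fu,
        censor_quarter=np.full(n, -1), death_quarter=np.full(n, -1))


def test_aggregate_closed_form_two_individuals():
    sim = _fake_sim([0.0, 1.0])
    agg = aggregate(sim, "cum_inc:mi", 5.0)
    assert agg["mean"] == pytest.approx(0.5)
    half = 1.96 * np.std([0.0, 1.0], ddof=1) / np.sqrt(2)
    assert agg["ci_hi"] - agg["mean"] == pytest.approx(half)
    identical = _fake_sim([0.3, 0.3, 0.3])
    agg = aggregate(identical, "cum_inc:mi", 5.0)
    assert agg["ci_hi"] == agg["ci_lo"] == agg["mean"]


def test_aggregate_requires_two_contributors():
    sim = _fake_sim([0.1, 0.2], follow_up=[31, 3])
    with pytest.raises(SimulationError):
        aggregate(sim, "cum_inc:mi", 5.0)


def test_censored_individuals_excluded_from_horizon_denominator():
    sim = _fake_sim([0.1, 0.2, 0.3], follow_up=[31, 31, 10])
    agg = aggregate(sim, "cum_inc:mi", 5.0)
    assert agg["n"] == 2
    assert agg["mean"] == pytest.approx(np.mean([0.1, 0.2]))


def test_contrast_constant_shift_gives_zero_width_interval():
    a = _fake_sim([0.10, 0.20, 0.30])
    b = _fake_sim([0.11, 0.21, 0.31])
    c = contrast({"SU": b, "DPP4i": a}, ("SU", "DPP4i"), "cum_inc:mi", 5.0)
    assert c.mean_diff == pytest.approx(0.01)
    assert c.ci_hi - c.ci_lo == pytest.approx(0.0, abs=1e-12)
    identical = contrast({"SU": a, "DPP4i": a}, ("SU", "DPP4i"),
                         "cum_inc:mi", 5.0)
    assert identical.mean_diff == 0.0
    assert identical.ci_lo == identical.ci_hi == 0.0


def test_contrast_requires_identical_individuals():
    a = _fake_sim([0.1, 0.2])
    b = _fake_sim([0.1, 0.2], ids=np.array(["x0", "x1"]))
    with pytest.raises(SimulationError, match="pairing"):
        contrast({"SU": a, "DPP4i": b}, ("SU", "DPP4i"), "cum_inc:mi", 5.0)


def test_subgroup_contrasts_average_to_overall(small_cohort, engines):
    equations, models, registry = engines
    tl = simulate_pathways(small_cohort, default_transition_spec(), seed=13)
    sims = run_counterfactual_cohort(small_cohort, tl, equations, models,
                                     registry)
    kw = dict(endpoint="cum_inc:hf_hospitalisation", horizon_years=3.0,
              cohort=small_cohort)
    overall = contrast(sims, ("SGLT2i", "SU"), subgroup="overall", **kw)
    cvd = contrast(sims, ("SGLT2i", "SU"), subgroup="CVD", **kw)
    nocvd = contrast(sims, ("SGLT2i", "SU"), subgroup="no-CVD", **kw)
    pooled = (cvd.mean_diff * cvd.n + nocvd.mean_diff * nocvd.n) / overall.n
    assert cvd.n + nocvd.n == overall.n
    assert pooled == pytest.approx(overall.mean_diff, abs=1e-12)


def test_contrast_table_cardinality(small_cohort, engines):
    equations, models, registry = engines
    tl = simulate_pathways(small_cohort, default_transition_spec(), seed=14)
    sims = run_counterfactual_cohort(small_cohort, tl, equations, models,
                                     registry)
    table = contrast_table(sims, ["cum_inc:eskd", "cum_inc:mi"],
                           horizons_years=(1.0, 5.0), cohort=small_cohort)
    assert len(table) == 3 * 2 * 2 * 3  # pairs x endpoints x horizons x subgroups


def test_death_dominance_in_stochastic_mode(small_cohort, engines):
    """After a simulated death no event probabilities are recorded and no
    occurrences appear."""
    equations, models, registry = engines
    models = dict(models)
    models["all_cause_death"] = EventModel("all_cause_death", intercept=-0.5,
                                           absorbing=True)
    tl = simulate_pathways(small_cohort, default_transition_spec(), seed=15)
    sim = run_cohort(small_cohort, tl, equations, models, registry,
                     mode="stochastic", seed=99)
    died = sim.death_quarter >= 0
    assert died.any()
    for i in np.nonzero(died)[0][:50]:
        dq = sim.death_quarter[i]
        assert np.isnan(sim.event_probs[i, dq + 1:, :]).all()
        assert not sim.occurrences[i, dq + 1:, :].any()
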