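"""Risk-factor engine: AR(1) dynamics, offsets, determinism."""

import numpy as np
import pytest

from t2dsim.cohort import RISK_FACTORS, RiskFactorVector
from t2dsim.effects import (EffectEstimate, EffectsRegistry,
                            default_effects_registry)
from t2dsim.errors import ConfigurationError
from t2dsim.pathways import HORIZON_QUARTERS, RegimenCode
from t2dsim.risk import (EquationSet, OffsetSchedule, RiskEquation,
                         apply_offsets, update_risk_factors)
from tests.conftest import make_profile


def identity_equations() -> EquationSet:
    return EquationSet({f: RiskEquation(f, intercept=0.0, lag1=1.0)
                        for f in RISK_FACTORS})


def zero_registry() -> EffectsRegistry:
    return EffectsRegistry([], warn_missing=False)


def test_identity_equations_are_a_fixed_point():
    profile = make_profile()
    out = update_risk_factors(profile.risk_factors, profile,
                              RegimenCode.NO_THERAPY, identity_equations(),
                              zero_registry())
    assert np.allclose(out.as_array(), profile.risk_factors.as_array())


def test_registry_shift_applies_exactly_once_per_quarter():
    profile = make_profile()
    reg = EffectsRegistry(
        [EffectEstimate("SGLT2i", "hba1c", "risk_factor_shift", -0.5)],
        warn_missing=False)
    out = update_risk_factors(profile.risk_factors, profile,
                              RegimenCode.SGLT2I_MONO, identity_equations(),
                              reg)
    assert out.hba1c == pytest.approx(profile.risk_factors.hba1c - 0.5)
    others = [f for f in RISK_FACTORS if f != "hba1c"]
    for f in others:
        assert getattr(out, f) == getattr(profile.risk_factors, f)


def test_ar1_stationary_mean_is_fixed_point():
    """hba1c: intercept 0.8, lag1 0.9 -> stationary mean 0.8/(1-0.9) = 8.0."""
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["hba1c"] = RiskEquation("hba1c", intercept=0.8, lag1=0.9)
    eqset = EquationSet(eqs)
    profile = make_profile()
    out = update_risk_factors(profile.risk_factors, profile,
                              RegimenCode.NO_THERAPY, eqset, zero_registry())
    assert out.hba1c == pytest.approx(8.0, abs=1e-12)


def test_ar1_convergence_to_closed_form_stationary_mean():
    """From any start, |x_t - a/(1-lag1)| < 1e-6 by quarter 200."""
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["hba1c"] = RiskEquation("hba1c", intercept=0.8, lag1=0.9)
    eqset = EquationSet(eqs)
    profile = make_profile(risk_factors=RiskFactorVector(
        hba1c=12.0, bmi=30, sbp=130, dbp=80, hdl=40, ldl=80,
        total_cholesterol=160, triglycerides_nonfasting=150, egfr=90))
    state = profile.risk_factors
    reg = zero_registry()
    for q in range(200):
        state = update_risk_factors(state, profile, RegimenCode.NO_THERAPY,
                                    eqset, reg, quarter=q)
    assert abs(state.hba1c - 8.0) < 1e-6


def test_expected_mode_is_deterministic_and_consumes_no_rng():
    profile = make_profile()
    eqset = EquationSet({f: RiskEquation(f, 0.5, 0.9, resid_sd=2.0)
                         for f in RISK_FACTORS})
    a = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.MET_SU, eqset,
                            default_effects_registry())
    b = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.MET_SU, eqset,
                            default_effects_registry())
    assert a == b


def test_stochastic_mode_adds_seeded_noise():
    profile = make_profile()
    eqset = EquationSet({f: RiskEquation(f, 0.0, 1.0, resid_sd=1.0)
                         for f in RISK_FACTORS})
    a = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, eqset, zero_registry(),
                            mode="stochastic", seed=5)
    b = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, eqset, zero_registry(),
                            mode="stochastic", seed=5)
    c = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, eqset, zero_registry(),
                            mode="stochastic", seed=6)
    assert a == b
    assert a != c


def test_missing_equation_errors_with_factor_name():
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS if f != "egfr"}
    with pytest.raises(ConfigurationError, match="egfr"):
        EquationSet(eqs)


def test_zero_offset_schedule_is_a_noop():
    profile = make_profile()
    eqset = identity_equations()
    shifted = apply_offsets(eqset, OffsetSchedule(
        "bmi", np.zeros(HORIZON_QUARTERS)))
    a = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, eqset, zero_registry())
    b = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, shifted, zero_registry())
    assert a == b


def test_constant_offset_shifts_prediction_linearly():
    profile = make_profile()
    base = identity_equations()
    shifted = apply_offsets(base, OffsetSchedule(
        "bmi", np.ones(HORIZON_QUARTERS)))
    a = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, base, zero_registry())
    b = update_risk_factors(profile.risk_factors, profile,
                            RegimenCode.NO_THERAPY, shifted, zero_registry())
    assert b.bmi == pytest.approx(a.bmi + 1.0)
    assert b.hba1c == a.hba1c


def test_offset_attach_is_idempotent_replace():
    base = identity_equations()
    s1 = OffsetSchedule("bmi", np.full(HORIZON_QUARTERS, 1.0))
    s2 = OffsetSchedule("bmi", np.full(HORIZON_QUARTERS, 2.0))
    eqset = apply_offsets(apply_offsets(base, s1), s2)
    assert eqset.offsets["bmi"].at(0) == 2.0
    again = apply_offsets(eqset, s2)
    assert again.offsets["bmi"].at(10) == 2.0


def test_offset_horizon_mismatch_rejected():
    with pytest.raises(ConfigurationError, match="horizon"):
        apply_offsets(identity_equations(), OffsetSchedule("bmi", np.zeros(7)))


def test_offset_linearity_against_forward_recursion_oracle():
    """With AR dynamics, prediction(offsets a+b) equals the brute-force
    recursion with both schedules summed, and differs from prediction(a) by
    the propagated contribution of b."""
    rng = np.random.default_rng(3)
    a = rng.normal(size=HORIZON_QUARTERS)
    b = rng.normal(size=HORIZON_QUARTERS)
    lag = 0.8
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["bmi"] = RiskEquation("bmi", intercept=30.0 * (1 - lag), lag1=lag)
    profile = make_profile()

    def run(offsets):
        eqset = EquationSet(eqs).with_offsets(OffsetSchedule("bmi", offsets))
        state = profile.risk_factors
        out = []
        for q in range(12):
            state = update_risk_factors(state, profile,
                                        RegimenCode.NO_THERAPY, eqset,
                                        zero_registry(), quarter=q)
            out.append(state.bmi)
        return np.array(out)

    # independent oracle: scalar forward recursion
    x, expect = 30.0, []
    for q in range(12):
        x = 30.0 * (1 - lag) + lag * x + a[q] + b[q]
        expect.append(x)
    assert np.allclose(run(a + b), expect, atol=1e-10)
    prop = np.array([sum(lag ** (q - s) * b[s] for s in range(q + 1))
                     for q in range(12)])
    assert np.allclose(run(a + b) - run(a), prop, atol=1e-10)


def test_clipping_at_physiologic_floor_is_counted():
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["egfr"] = RiskEquation("egfr", intercept=-500.0, lag1=1.0)
    eqset = EquationSet(eqs)
    profile = make_profile()
    out = update_risk_factors(profile.risk_factors, profile,
                              RegimenCode.NO_THERAPY, eqset, zero_registry())
    assert out.egfr == pytest.approx(1.0)  # documented eGFR floor
    assert eqset.clip_count >= 1
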