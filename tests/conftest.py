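"""Shared fixtures: full-size and small synthetic cohorts, engine defaults,
and helpers for single-individual scenarios."""

import numpy as np
import pytest

from t2dsim.cohort import (BaselineProfile, RiskFactorVector,
                           default_cohort_spec, generate_cohort)
from t2dsim.effects import default_effects_registry
from t2dsim.events import default_event_models
from t2dsim.pathways import (PathwayTimeline, RegimenCode,
                             default_transition_spec, simulate_pathways)
from t2dsim.risk import default_risk_equations

FULL_N = 62_640
SEED = 20_260_922 % 2**31


@pytest.fixture(scope="session")
def table1_cohort():
    """Full-size cohort from the published-summary-calibrated spec."""
    return generate_cohort(default_cohort_spec(), seed=SEED)


@pytest.fixture(scope="session")
def table1_timelines(table1_cohort):
    return simulate_pathways(table1_cohort, default_transition_spec(),
                             seed=SEED + 1)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_cohort_spec(2_000), seed=3)


@pytest.fixture(scope="session")
def engines():
    return (default_risk_equations(), default_event_models(),
            default_effects_registry())


def make_profile(**overrides) -> BaselineProfile:
    base = dict(
        id="p0", age=60.0, sex="male", ethnicity="White", imd_quintile="3",
        years_since_diagnosis=5.0,
        risk_factors=RiskFactorVector(
            hba1c=8.0, bmi=30.0, sbp=130.0, dbp=80.0, hdl=40.0, ldl=80.0,
            total_cholesterol=160.0, triglycerides_nonfasting=150.0,
            egfr=90.0),
        history_flags={"angina": False, "mi": False, "stroke": False,
                       "hf": False, "hypoglycaemia": False},
        second_line_class="SU",
    )
    base.update(overrides)
    return BaselineProfile(**base)


def make_timeline(n_quarters: int, regimen=RegimenCode.MET_SU,
                  censor_quarter=None, id="p0") -> PathwayTimeline:
    return PathwayTimeline(
        id=id,
        regimens=np.full(n_quarters, int(regimen), dtype=np.int8),
        statin=np.zeros(n_quarters, dtype=bool),
        bp_lowering=np.zeros(n_quarters, dtype=bool),
        censor_quarter=censor_quarter,
    )
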