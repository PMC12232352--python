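"""Hold-out split, agreement assessment, offset recovery and coverage."""

import numpy as np
import pandas as pd
import pytest

from t2dsim.calibrate import (assess_agreement, mean_trajectories,
                              observed_trajectories, recalibrate,
                              split_holdout)
from t2dsim.cohort import RISK_FACTORS, default_cohort_spec, generate_cohort
from t2dsim.effects import EffectsRegistry
from t2dsim.errors import ConfigurationError
from t2dsim.events import EventModel
from t2dsim.pathways import (HORIZON_QUARTERS, RegimenCode, TimelineSet)
from t2dsim.risk import (EquationSet, OffsetSchedule, RiskEquation,
                         apply_offsets, default_risk_equations)
from t2dsim.simulate import run_cohort
from t2dsim.effects import EVENTS
from tests.conftest import make_timeline


def _uncensored_timelines(cohort, n_quarters=HORIZON_QUARTERS):
    from t2dsim.pathways import SECOND_LINE_DUAL
    n = len(cohort)
    own = np.array([int(SECOND_LINE_DUAL[c])
                    for c in cohort.frame["second_line_class"]], dtype=np.int8)
    reg = np.repeat(own[:, None], n_quarters, axis=1)
    return TimelineSet(cohort.frame["id"].to_numpy(), reg,
                       np.zeros((n, n_quarters), bool),
                       np.zeros((n, n_quarters), bool),
                       np.full(n, -1, dtype=np.int16))


def _models():
    # effectively event-free: keeps stochastic runs alive throughout, so
    # trajectory comparisons are not truncated by simulated deaths
    return {name: EventModel(name, intercept=-50.0) for name in EVENTS}


def zero_registry():
    return EffectsRegistry([], warn_missing=False)


# -- split ------------------------------------------------------------------

def test_split_is_a_stratified_partition():
    cohort = generate_cohort(default_cohort_spec(100), seed=1)
    dev, hold = split_holdout(cohort, 0.5, seed=2)
    assert len(dev) + len(hold) == 100
    assert set(dev.frame["id"]).isdisjoint(hold.frame["id"])
    for arm, total in cohort.frame["second_line_class"].value_counts().items():
        in_hold = (hold.frame["second_line_class"] == arm).sum()
        assert abs(in_hold - total / 2) <= 1  # stratum split off by <= 1


def test_split_is_seed_deterministic():
    cohort = generate_cohort(default_cohort_spec(200), seed=1)
    a = split_holdout(cohort, 0.3, seed=5)[1].frame
    b = split_holdout(cohort, 0.3, seed=5)[1].frame
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ConfigurationError):
        split_holdout(cohort, 1.0, seed=5)


# -- agreement --------------------------------------------------------------

def _pred_frame(mean, sd=1.0, n=100, quarters=8, outcome="bmi"):
    return pd.DataFrame({"outcome": outcome, "quarter": range(quarters),
                         "mean": mean, "sd": sd, "n": n})


def _obs_frame(mean, quarters=8, n=100, outcome="bmi"):
    return pd.DataFrame({"outcome": outcome, "quarter": range(quarters),
                         "observed_mean": mean, "n": n})


def test_observed_equal_to_predicted_gives_full_agreement():
    pred = _pred_frame(30.0)
    report = assess_agreement(pred, _obs_frame(30.0))
    assert (report.table["agree"]).all()
    assert report.summary["agreement_fraction"].iloc[0] == 1.0
    assert report.flagged == []


def test_observed_far_outside_band_is_flagged():
    pred = _pred_frame(30.0, sd=1.0, n=100)
    half = 1.96 * 1.0 / np.sqrt(100)
    report = assess_agreement(pred, _obs_frame(30.0 + 10 * half))
    assert not report.table["agree"].any()
    assert report.summary["agreement_fraction"].iloc[0] == 0.0
    assert report.flagged == ["bmi"]


def test_grid_mismatch_rejected():
    pred = _pred_frame(30.0, quarters=8)
    with pytest.raises(ConfigurationError, match="grid"):
        assess_agreement(pred, _obs_frame(30.0, quarters=6))


def test_agreement_band_attains_nominal_coverage():
    """With observed means drawn from the predictive distribution, the
    95% band covers the observed mean ~95% of the time (93-97% empirically,
    pooled over replicates and quarters)."""
    quarters = 9
    n_dev, n_obs, reps = 3_000, 150, 200
    dev = generate_cohort(default_cohort_spec(n_dev), seed=31)
    obs_pop = generate_cohort(default_cohort_spec(n_obs * reps), seed=32)
    equations = default_risk_equations()
    models = _models()
    sim_dev = run_cohort(dev, _uncensored_timelines(dev, quarters), equations,
                         models, zero_registry(), mode="stochastic", seed=33)
    pred = mean_trajectories(sim_dev, outcomes=("hba1c",))
    sim_obs = run_cohort(obs_pop, _uncensored_timelines(obs_pop, quarters),
                         equations, models, zero_registry(),
                         mode="stochastic", seed=34)
    traj = sim_obs.factors[:, :, RISK_FACTORS.index("hba1c")]
    hits = 0
    total = 0
    half = 1.96 * pred["sd"].to_numpy() / np.sqrt(n_obs)
    centre = pred["mean"].to_numpy()
    for r in range(reps):
        grp = traj[r * n_obs:(r + 1) * n_obs]
        obs_mean = grp.mean(axis=0)
        hits += int(np.sum(np.abs(obs_mean - centre) <= half))
        total += quarters
    coverage = hits / total
    assert 0.93 <= coverage <= 0.97, coverage


# -- recalibration ----------------------------------------------------------

def test_constant_level_discrepancy_is_reproduced_exactly():
    """Observed = predicted + c from quarter 1 onward: applying the
    recovered schedule reproduces the observed means exactly."""
    lag = 0.9
    eqs = {f: RiskEquation(f, 0.0, 1.0) for f in RISK_FACTORS}
    eqs["bmi"] = RiskEquation("bmi", intercept=30.0 * (1 - lag), lag1=lag)
    eqset = EquationSet(eqs)
    quarters = 12
    pred = _pred_frame([30.0] * quarters, quarters=quarters)
    c = 2.0
    obs = _obs_frame([30.0] + [30.0 + c] * (quarters - 1), quarters=quarters)
    schedules = recalibrate(eqset, pred, obs, ["bmi"])
    delta = schedules["bmi"].offsets
    # replay the AR recursion with the offsets: discrepancy trajectory
    D = 0.0
    for q in range(quarters - 1):
        D = lag * D + delta[q]
        assert D == pytest.approx(obs["observed_mean"][q + 1] - 30.0,
                                  abs=1e-10)


def test_zero_discrepancy_gives_zero_offsets():
    pred = _pred_frame(np.linspace(30, 31, 8))
    obs = _obs_frame(np.linspace(30, 31, 8))
    schedules = recalibrate(default_risk_equations(), pred, obs, ["bmi"])
    assert np.allclose(schedules["bmi"].offsets, 0.0, atol=1e-12)


def test_flagging_and_recalibration_preconditions():
    pred = _pred_frame(30.0)
    obs = _obs_frame(30.0)
    with pytest.raises(ConfigurationError):
        recalibrate(default_risk_equations(), pred, obs, [])
    with pytest.raises(ConfigurationError):
        recalibrate(default_risk_equations(), pred, obs, ["eskd"])
    with pytest.raises(ConfigurationError, match="window"):
        recalibrate(default_risk_equations(),
                    _pred_frame(30.0, quarters=3),
                    _obs_frame(30.0, quarters=3), ["bmi"], window=4)


def _drift_recovery(n_holdout, quarters=21, drift_rate=0.05, seed=41):
    """Inject an additive per-quarter drift of drift_rate*t into the 'true'
    BMI update, observe a stochastic hold-out, and recover the schedule."""
    equations = default_risk_equations()
    truth = apply_offsets(equations, OffsetSchedule(
        "bmi", drift_rate * np.arange(HORIZON_QUARTERS, dtype=float)))
    dev = generate_cohort(default_cohort_spec(n_holdout), seed=seed)
    hold = generate_cohort(default_cohort_spec(n_holdout), seed=seed + 1)
    models = _models()
    pred = mean_trajectories(
        run_cohort(dev, _uncensored_timelines(dev, quarters), equations,
                   models, zero_registry()), outcomes=("bmi",))
    obs = observed_trajectories(
        run_cohort(hold, _uncensored_timelines(hold, quarters), truth,
                   models, zero_registry(), mode="stochastic", seed=seed + 2),
        outcomes=("bmi",))
    recovered = recalibrate(equations, pred, obs, ["bmi"],
                            window=3)["bmi"].offsets[:quarters - 1]
    target = drift_rate * np.arange(quarters - 1, dtype=float)
    return recovered, target


def test_linear_drift_recovered_within_tolerance():
    recovered, target = _drift_recovery(10_000)
    rmse = np.sqrt(np.mean((recovered - target) ** 2))
    assert rmse <= 0.2 * np.sqrt(np.mean(target ** 2))
    # pointwise recovery of the 0.05*t schedule away from the smoothing edges
    assert np.max(np.abs(recovered[2:-2] - target[2:-2])) < 0.02


def test_recovery_improves_with_holdout_size():
    rec_small, target = _drift_recovery(1_000, seed=51)
    rec_large, _ = _drift_recovery(10_000, seed=51)
    rmse_small = np.sqrt(np.mean((rec_small - target) ** 2))
    rmse_large = np.sqrt(np.mean((rec_large - target) ** 2))
    assert rmse_large < rmse_small


def test_recalibrated_matching_system_yields_zero_offsets():
    """Idempotence: once predictions match observations, another round of
    recalibration returns (numerically) zero offsets."""
    equations = default_risk_equations()
    quarters = 12
    dev = generate_cohort(default_cohort_spec(2_000), seed=61)
    sim = run_cohort(dev, _uncensored_timelines(dev, quarters), equations,
                     _models(), zero_registry())
    pred = mean_trajectories(sim, outcomes=("bmi",))
    obs = observed_trajectories(sim, outcomes=("bmi",))
    schedules = recalibrate(equations, pred, obs, ["bmi"])
    assert np.allclose(schedules["bmi"].offsets, 0.0, atol=1e-10)
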