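"""Stage 3: agreement assessment and recalibration, validated by
parameter recovery on synthetic data.

A known per-quarter drift is injected into the BMI update equation of a
"true" system; a stochastic hold-out sample simulated under the truth plays
the role of observed data.  The unadjusted model's predictions are compared
against the observed means (agreement bands), BMI is flagged, and the
additive offset schedule is recovered and checked against the injected
ground truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from t2dsim import default_cohort_spec, generate_cohort
from t2dsim.calibrate import (assess_agreement, mean_trajectories,
                              observed_trajectories, recalibrate)
from t2dsim.effects import EVENTS, EffectsRegistry
from t2dsim.events import EventModel
from t2dsim.pathways import HORIZON_QUARTERS, SECOND_LINE_DUAL, TimelineSet
from t2dsim.risk import OffsetSchedule, apply_offsets, default_risk_equations
from t2dsim.simulate import run_cohort

DRIFT_RATE = 0.05  # kg/m2 per quarter of elapsed time, injected into BMI
QUARTERS = 21      # five years of observation


def uncensored(cohort, quarters):
    n = len(cohort)
    own = np.array([int(SECOND_LINE_DUAL[c])
                    for c in cohort.frame["second_line_class"]], dtype=np.int8)
    return TimelineSet(cohort.frame["id"].to_numpy(),
                       np.repeat(own[:, None], quarters, axis=1),
                       np.zeros((n, quarters), bool),
                       np.zeros((n, quarters), bool),
                       np.full(n, -1, dtype=np.int16))


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--n-holdout", type=int, default=10_000)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    equations = default_risk_equations()
    truth = apply_offsets(equations, OffsetSchedule(
        "bmi", DRIFT_RATE * np.arange(HORIZON_QUARTERS, dtype=float)))
    models = {name: EventModel(name, intercept=-50.0) for name in EVENTS}
    registry = EffectsRegistry([], warn_missing=False)

    # the predictive band needs the model's across-individual spread, so the
    # development run is stochastic and four times the hold-out size
    dev = generate_cohort(default_cohort_spec(4 * args.n_holdout),
                          seed=args.seed)
    hold = generate_cohort(default_cohort_spec(args.n_holdout),
                           seed=args.seed + 1)
    pred = mean_trajectories(
        run_cohort(dev, uncensored(dev, QUARTERS), equations, models,
                   registry, mode="stochastic", seed=args.seed + 3),
        outcomes=("bmi", "hba1c", "sbp"))
    obs = observed_trajectories(
        run_cohort(hold, uncensored(hold, QUARTERS), truth, models, registry,
                   mode="stochastic", seed=args.seed + 2),
        outcomes=("bmi", "hba1c", "sbp"))

    # fraction rule: tolerate isolated sampling excursions, flag sustained
    # departures (the any-quarter default is the stricter option)
    report = assess_agreement(pred, obs, rule="fraction", min_fraction=0.8)
    report.table.to_csv(args.out / "calibration_table.csv", index=False)
    report.summary.to_csv(args.out / "calibration_summary.csv", index=False)
    print("agreement fractions (share of quarters inside the 95% band):")
    for row in report.summary.itertuples():
        tag = "FLAGGED" if row.flagged else "ok"
        print(f"  {row.outcome:<8} {row.agreement_fraction:5.2f}  {tag}")

    schedules = recalibrate(equations, pred, obs, report.flagged, window=3)
    target = DRIFT_RATE * np.arange(QUARTERS - 1, dtype=float)
    recovered = schedules["bmi"].offsets[:QUARTERS - 1]
    rmse = float(np.sqrt(np.mean((recovered - target) ** 2)))
    rel = rmse / float(np.sqrt(np.mean(target ** 2)))
    pd.DataFrame({"quarter": np.arange(QUARTERS - 1),
                  "injected_offset": target,
                  "recovered_offset": recovered}).to_csv(
        args.out / "calibration_recovery.csv", index=False)
    print(f"injected BMI drift {DRIFT_RATE} * t recovered with "
          f"RMSE {rmse:.4f} ({100 * rel:.1f} % of drift magnitude) at "
          f"hold-out n = {args.n_holdout}")
    print(f"wrote calibration_table.csv, calibration_summary.csv, "
          f"calibration_recovery.csv under {args.out}")


if __name__ == "__main__":
    main()
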