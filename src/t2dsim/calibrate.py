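"""Hold-out agreement assessment and risk-equation recalibration.

Predicted mean trajectories (with the spread across individuals) are
compared quarter by quarter against observed hold-out means; "agreement"
means the observed mean lies inside the 95% predicted interval
``pred_mean +/- 1.96 * pred_sd / sqrt(n_obs)``.  An outcome whose observed
trajectory exits the band (by default in any quarter) is flagged and
receives an additive per-quarter offset schedule.

The offsets are estimated by inverting the AR recursion: with level
discrepancies ``D_t = observed_mean_t - predicted_mean_t`` (optionally
smoothed by a centred moving window), the update-equation offset that
reproduces them exactly is ``delta_t = D_{t+1} - lag1 * D_t``.  Because each
quarter has its own free offset this is also the least-squares solution;
re-running with the schedule attached restores agreement up to smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RISK_FACTORS, Cohort
from .errors import ConfigurationError
from .pathways import HORIZON_QUARTERS
from .risk import EquationSet, OffsetSchedule
from .simulate import CohortSimulation, Z95

__all__ = [
    "split_holdout",
    "CalibrationReport",
    "mean_trajectories",
    "assess_agreement",
    "recalibrate",
]


def split_holdout(cohort: Cohort, fraction: float,
                  seed: int) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive development/hold-out split, stratified by
    second-line class; deterministic under a fixed seed.  ``fraction`` is the
    hold-out share."""
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("hold-out fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA1]))
    frame = cohort.frame
    holdout_idx = []
    for _, grp in frame.groupby("second_line_class", sort=True):
        k = int(round(fraction * len(grp)))
        pick = rng.permutation(len(grp))[:k]
        holdout_idx.append(grp.index.to_numpy()[pick])
    holdout_idx = np.concatenate(holdout_idx) if holdout_idx else np.array([])
    mask = frame.index.isin(holdout_idx)
    dev = Cohort(frame.loc[~mask].reset_index(drop=True))
    hold = Cohort(frame.loc[mask].reset_index(drop=True))
    return dev, hold


@dataclass
class CalibrationReport:
    """Per-quarter band comparison plus a per-outcome verdict."""

    table: pd.DataFrame    # outcome, quarter, predicted_mean, ci_lo, ci_hi,
    #                        observed_mean, agree
    summary: pd.DataFrame  # outcome, agreement_fraction, flagged

    @property
    def flagged(self) -> list[str]:
        return list(self.summary.loc[self.summary["flagged"], "outcome"])


def mean_trajectories(sim: CohortSimulation,
                      outcomes=RISK_FACTORS) -> pd.DataFrame:
    """Per-quarter mean and across-individual sd of each risk factor among
    individuals still under follow-up (long format)."""
    rows = []
    for f in outcomes:
        traj = sim.factors[:, :, RISK_FACTORS.index(f)]
        for q in range(sim.n_quarters):
            col = traj[:, q]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            rows.append({"outcome": f, "quarter": q,
                         "mean": float(np.mean(col)),
                         "sd": float(np.std(col, ddof=1)) if col.size > 1 else 0.0,
                         "n": int(col.size)})
    return pd.DataFrame(rows)


def observed_trajectories(sim: CohortSimulation,
                          outcomes=RISK_FACTORS) -> pd.DataFrame:
    """Observed-style means (no sd) from a simulation standing in for
    measured hold-out data."""
    df = mean_trajectories(sim, outcomes)
    return df[["outcome", "quarter", "mean", "n"]].rename(
        columns={"mean": "observed_mean"})


def assess_agreement(predicted: pd.DataFrame, observed: pd.DataFrame,
                     rule: str = "any_quarter",
                     min_fraction: float = 0.95) -> CalibrationReport:
    """Compare predicted bands with observed means on an aligned quarter grid.

    ``predicted`` columns: outcome, quarter, mean, sd, n;
    ``observed`` columns: outcome, quarter, observed_mean, n.  The 95%
    predicted interval for the observed mean of n_obs individuals is
    ``mean +/- 1.96 sd / sqrt(n_obs)``.  Flagging rule: ``"any_quarter"``
    (default — one excursion flags the outcome) or ``"fraction"`` (flag when
    the agreement fraction falls below ``min_fraction``).
    """
    merged = predicted.merge(observed, on=["outcome", "quarter"],
                             how="outer", suffixes=("_pred", "_obs"),
                             indicator=True)
    if (merged["_merge"] != "both").any():
        raise ConfigurationError(
            "predicted and observed trajectories are on different "
            "outcome/quarter grids")
    half = Z95 * merged["sd"] / np.sqrt(merged["n_obs"])
    table = pd.DataFrame({
        "outcome": merged["outcome"],
        "quarter": merged["quarter"],
        "predicted_mean": merged["mean"],
        "ci_lo": merged["mean"] - half,
        "ci_hi": merged["mean"] + half,
        "observed_mean": merged["observed_mean"],
    })
    table["agree"] = ((table["observed_mean"] >= table["ci_lo"])
                      & (table["observed_mean"] <= table["ci_hi"]))
    rows = []
    for outcome, grp in table.groupby("outcome", sort=False):
        frac = float(grp["agree"].mean())
        flagged = (not grp["agree"].all()) if rule == "any_quarter" \
            else frac < min_fraction
        rows.append({"outcome": outcome, "agreement_fraction": frac,
                     "flagged": flagged})
    return CalibrationReport(table=table.reset_index(drop=True),
                             summary=pd.DataFrame(rows))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Local-polynomial (Savitzky-Golay, order <= 2) smoothing: averages
    noise over the window while passing linear and quadratic discrepancy
    trends through unchanged, including at the boundaries."""
    if window <= 1:
        return values
    from scipy.signal import savgol_filter
    window = min(window if window % 2 == 1 else window + 1, len(values))
    return savgol_filter(values, window_length=window,
                         polyorder=min(2, window - 1), mode="interp")


def recalibrate(equations: EquationSet, predicted: pd.DataFrame,
                observed: pd.DataFrame, flagged: list[str],
                window: int = 1,
                horizon: int = HORIZON_QUARTERS) -> dict[str, OffsetSchedule]:
    """Estimate an additive offset schedule per flagged risk factor.

    Only risk-factor outcomes are recalibratable.  The last estimated offset
    is carried forward through quarters beyond the observed grid.
    """
    if not flagged:
        raise ConfigurationError("no outcomes flagged for recalibration")
    schedules = {}
    for outcome in flagged:
        if outcome not in RISK_FACTORS:
            raise ConfigurationError(
                f"only risk factors are recalibratable, not {outcome!r}")
        pred = predicted[predicted["outcome"] == outcome].sort_values("quarter")
        obs = observed[observed["outcome"] == outcome].sort_values("quarter")
        quarters = pred["quarter"].to_numpy()
        if not np.array_equal(quarters, obs["quarter"].to_numpy()):
            raise ConfigurationError(f"grid mismatch for {outcome!r}")
        if len(quarters) <= max(window, 1):
            raise ConfigurationError(
                f"fewer observed quarters than the smoothing window for "
                f"{outcome!r}")
        D = obs["observed_mean"].to_numpy() - pred["mean"].to_numpy()
        D = _smooth(D, window)
        lag1 = equations.equations[outcome].lag1
        delta = D[1:] - lag1 * D[:-1]
        offsets = np.zeros(horizon)
        T = min(len(delta), horizon)
        offsets[:T] = delta[:T]
        if T < horizon and T > 0:
            offsets[T:] = delta[T - 1]
        schedules[outcome] = OffsetSchedule(outcome, offsets)
    return schedules
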