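"""CSV/YAML/JSON serialisation of cohorts, timelines, specs and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec
from .pathways import HORIZON_QUARTERS, RegimenCode, TimelineSet, TransitionSpec

__all__ = [
    "write_cohort_csv", "read_cohort_csv",
    "write_timelines_csv", "read_timelines_csv",
    "write_cohort_spec", "read_cohort_spec",
    "write_transition_spec", "read_transition_spec",
    "write_manifest",
]


def write_cohort_csv(cohort: Cohort, path, spec: CohortSpec | None = None,
                     seed: int | None = None) -> None:
    """One row per individual; a sidecar ``<path>.spec.json`` records the
    generating spec and seed when given."""
    path = Path(path)
    cohort.frame.to_csv(path, index=False)
    if spec is not None:
        sidecar = {"seed": seed, "spec": spec.to_dict(),
                   "package_version": __version__}
        path.with_suffix(path.suffix + ".spec.json").write_text(
            json.dumps(sidecar, indent=2))


def read_cohort_csv(path) -> Cohort:
    frame = pd.read_csv(path, dtype={"imd_quintile": str})
    for col in frame.columns:
        if col.startswith("history_") or col == "cvd_history":
            frame[col] = frame[col].astype(bool)
    return Cohort(frame)


def write_timelines_csv(timelines: TimelineSet, path) -> None:
    timelines.to_frame().to_csv(path, index=False)


def read_timelines_csv(path, n_quarters: int = HORIZON_QUARTERS) -> TimelineSet:
    df = pd.read_csv(path)
    ids = df["id"].drop_duplicates().to_numpy()
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    reg = np.full((n, n_quarters), -1, dtype=np.int8)
    st = np.zeros((n, n_quarters), dtype=bool)
    bp = np.zeros((n, n_quarters), dtype=bool)
    rows = df["id"].map(index).to_numpy()
    quarters = df["quarter"].to_numpy()
    reg[rows, quarters] = [int(RegimenCode[r]) for r in df["regimen"]]
    st[rows, quarters] = df["statin"].to_numpy(dtype=bool)
    bp[rows, quarters] = df["bp_lowering"].to_numpy(dtype=bool)
    fu = df.groupby("id", sort=False)["quarter"].max().reindex(ids).to_numpy() + 1
    cq = np.where(fu >= n_quarters, -1, fu).astype(np.int16)
    return TimelineSet(ids, reg, st, bp, cq)


def write_cohort_spec(spec: CohortSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_cohort_spec(path) -> CohortSpec:
    return CohortSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_transition_spec(spec: TransitionSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_transition_spec(path) -> TransitionSpec:
    return TransitionSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path, *, seed: int, n: int, horizon_years: float,
                   cohort_spec: CohortSpec, transition_spec: TransitionSpec,
                   extra: dict | None = None) -> None:
    """Everything needed to reproduce a run byte-identically."""
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "n": int(n),
        "horizon_years": float(horizon_years),
        "cohort_spec": cohort_spec.to_dict(),
        "transition_spec": transition_spec.to_dict(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
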