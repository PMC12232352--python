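"""Per-drug-class treatment effects and their resolution for regimens.

Each drug class carries, relative to no therapy, an additive shift per risk
factor (the indirect pathway, applied inside the risk-factor update) and a
log hazard-ratio per complication (the direct pathway, added to the event
linear predictor).  A regimen's combined effect is the sum of its component
classes' effects on the transformed scale; the triple-or-other category is
resolved through a configured representative composition.

The shipped default values are illustrative placeholders whose *signs*
follow the meta-analytic literature (SGLT2i lower HbA1c, body weight and
heart-failure / kidney-event hazards; sulphonylureas raise hypoglycaemia
hazard); magnitudes are not authoritative and are fully config-driven.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import RISK_FACTORS
from .errors import ConfigurationError
from .pathways import REGIMEN_COMPONENTS, RegimenCode

__all__ = [
    "EVENTS",
    "DRUG_CLASSES",
    "EffectEstimate",
    "EffectsRegistry",
    "load_effects",
    "regimen_effect",
    "effect_matrix",
    "default_effects_registry",
]

logger = logging.getLogger(__name__)

#: Modelled complication processes (event-scale targets).
EVENTS = (
    "hypoglycaemia",
    "mi",
    "unstable_angina",
    "stroke",
    "hf_hospitalisation",
    "lea",
    "eskd",
    "eye_disease",
    "all_cause_death",
)

DRUG_CLASSES = ("metformin", "SU", "DPP4i", "SGLT2i", "GLP1RA", "TZD", "insulin")

RISK_FACTOR_SHIFT = "risk_factor_shift"
LOG_HAZARD_RATIO = "log_hazard_ratio"


@dataclass(frozen=True)
class EffectEstimate:
    drug_class: str
    target: str
    effect_type: str
    value: float
    source: str = ""

    def __post_init__(self):
        if self.drug_class not in DRUG_CLASSES:
            raise ConfigurationError(f"unknown drug class {self.drug_class!r}")
        if self.target in RISK_FACTORS:
            expected = RISK_FACTOR_SHIFT
        elif self.target in EVENTS:
            expected = LOG_HAZARD_RATIO
        else:
            raise ConfigurationError(f"unknown effect target {self.target!r}")
        if self.effect_type != expected:
            raise ConfigurationError(
                f"effect_type {self.effect_type!r} inconsistent with target "
                f"{self.target!r} (expected {expected!r})")
        if not np.isfinite(self.value):
            raise ConfigurationError(
                f"effect value for ({self.drug_class}, {self.target}) "
                "must be finite")


class EffectsRegistry:
    """Complete mapping (drug class, target) -> effect vs. no therapy.

    Missing pairs are filled with zeros (one warning per fill).  The
    combination rule for multi-drug regimens is additive on the transformed
    scale; a ``combine_hook(values) -> float`` may override it.
    """

    def __init__(self, estimates: Iterable[EffectEstimate] = (),
                 triple_composition: tuple[str, ...] = ("metformin", "SU", "DPP4i"),
                 combine_hook: Callable[[list[float]], float] | None = None,
                 warn_missing: bool = True):
        for cls in triple_composition:
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(
                    f"unknown class {cls!r} in triple composition")
        self.triple_composition = tuple(triple_composition)
        self.combine_hook = combine_hook
        self._table: dict[tuple[str, str], EffectEstimate] = {}
        self.fill_warnings = 0
        for est in estimates:
            self._table[(est.drug_class, est.target)] = est
        self._fill_missing(warn_missing)

    def _fill_missing(self, warn: bool = True) -> None:
        targets = (*RISK_FACTORS, *EVENTS)
        for cls in DRUG_CLASSES:
            for target in targets:
                if (cls, target) not in self._table:
                    etype = (RISK_FACTOR_SHIFT if target in RISK_FACTORS
                             else LOG_HAZARD_RATIO)
                    self._table[(cls, target)] = EffectEstimate(
                        cls, target, etype, 0.0, source="default-zero")
                    self.fill_warnings += 1
        if self.fill_warnings and warn:
            logger.warning("effects registry: %d (class, target) pairs "
                           "defaulted to zero", self.fill_warnings)

    def effect(self, drug_class: str, target: str) -> float:
        try:
            return self._table[(drug_class, target)].value
        except KeyError:
            raise ConfigurationError(
                f"no effect entry for ({drug_class!r}, {target!r})") from None

    def estimate(self, drug_class: str, target: str) -> EffectEstimate:
        return self._table[(drug_class, target)]

    def scaled(self, factor: float) -> "EffectsRegistry":
        """Registry with every effect value multiplied by ``factor``."""
        return EffectsRegistry(
            [EffectEstimate(e.drug_class, e.target, e.effect_type,
                            factor * e.value, e.source)
             for e in self._table.values()],
            triple_composition=self.triple_composition,
            combine_hook=self.combine_hook)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"drug_class": e.drug_class, "target": e.target,
                 "effect_type": e.effect_type, "value": e.value,
                 "source": e.source} for e in self._table.values()]
        return (pd.DataFrame(rows)
                .sort_values(["drug_class", "target"])
                .reset_index(drop=True))


def load_effects(config) -> EffectsRegistry:
    """Build a registry from a flat table.

    Accepts a DataFrame, a path to a CSV, or an iterable of mappings with
    columns/keys: drug_class, target, effect_type, value[, source].
    Malformed entries raise :class:`ConfigurationError` naming the offender;
    pairs absent from the table default to zero with a logged warning.
    """
    if isinstance(config, (str,)) or hasattr(config, "read"):
        config = pd.read_csv(config)
    if isinstance(config, pd.DataFrame):
        records = config.to_dict("records")
    else:
        records = list(config)
    estimates = []
    for rec in records:
        try:
            estimates.append(EffectEstimate(
                drug_class=str(rec["drug_class"]),
                target=str(rec["target"]),
                effect_type=str(rec["effect_type"]),
                value=float(rec["value"]),
                source=str(rec.get("source", "") or ""),
            ))
        except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
            raise ConfigurationError(
                f"malformed effects entry {rec!r}: {exc}") from exc
    return EffectsRegistry(estimates)


def _components(regimen: RegimenCode,
                registry: EffectsRegistry) -> tuple[str, ...]:
    comp = REGIMEN_COMPONENTS[RegimenCode(regimen)]
    if comp is None:  # triple_or_other
        return registry.triple_composition
    return comp


def regimen_effect(regimen: RegimenCode, target: str,
                   registry: EffectsRegistry) -> float:
    """Combined effect of a regimen versus no therapy on one target.

    Additive over component classes (risk-factor scale for risk factors,
    log-hazard scale for events); no therapy maps to exactly 0.
    """
    if target not in RISK_FACTORS and target not in EVENTS:
        raise ConfigurationError(f"unknown effect target {target!r}")
    values = [registry.effect(cls, target)
              for cls in _components(regimen, registry)]
    if registry.combine_hook is not None:
        return float(registry.combine_hook(values))
    return float(sum(values))


def effect_matrix(registry: EffectsRegistry,
                  targets: tuple[str, ...]) -> np.ndarray:
    """(n_regimen_codes, n_targets) lookup of combined effects, for the
    vectorised engines."""
    out = np.zeros((len(RegimenCode), len(targets)))
    for code in RegimenCode:
        for j, target in enumerate(targets):
            out[int(code), j] = regimen_effect(code, target, registry)
    return out


# Steady-state (long-run on-treatment) displacement targets, in the units of
# each risk factor, taken as round literature-scale magnitudes.  The registry
# stores the per-quarter increment (1 - lag1) * displacement so the default
# AR(1) engine (lag1 = 0.9) settles at the displacement while on the drug.
_AR1_LAG = 0.9
_STEADY_STATE_SHIFTS = {
    # hba1c %, bmi kg/m2, sbp/dbp mm Hg, egfr mL/min/1.73m2
    "metformin": {"hba1c": -1.0, "bmi": -0.5},
    "SU": {"hba1c": -0.8, "bmi": +1.0},
    "DPP4i": {"hba1c": -0.6},
    "SGLT2i": {"hba1c": -0.9, "bmi": -1.5, "sbp": -4.0, "dbp": -2.0,
               "egfr": +1.0},
    "GLP1RA": {"hba1c": -1.0, "bmi": -2.5},
    "TZD": {"hba1c": -0.8, "bmi": +2.0},
    "insulin": {"hba1c": -1.1, "bmi": +2.0},
}

_DIRECT_LOG_HRS = {
    "SU": {"hypoglycaemia": +1.0},
    "insulin": {"hypoglycaemia": +1.2},
    "SGLT2i": {"hf_hospitalisation": -0.35, "eskd": -0.45},
    "TZD": {"hf_hospitalisation": +0.30},
}


def default_effects_registry() -> EffectsRegistry:
    """Illustrative literature-signed default effects (see module docstring)."""
    estimates = []
    for cls, shifts in _STEADY_STATE_SHIFTS.items():
        for factor, shift in shifts.items():
            estimates.append(EffectEstimate(
                cls, factor, RISK_FACTOR_SHIFT,
                (1.0 - _AR1_LAG) * shift, source="illustrative-default"))
    for cls, hrs in _DIRECT_LOG_HRS.items():
        for event, loghr in hrs.items():
            estimates.append(EffectEstimate(
                cls, event, LOG_HAZARD_RATIO, loghr,
                source="illustrative-default"))
    reg = EffectsRegistry(estimates, warn_missing=False)
    reg.fill_warnings = 0  # sparse defaults are deliberate, not omissions
    return reg
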