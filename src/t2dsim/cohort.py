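"""Synthetic baseline cohort generation for the second-line treatment population.

Individual-level records (people with type 2 diabetes presenting for a
second-line glucose-lowering drug added to metformin) are synthesised so
that each variable's marginal summary matches a published summary table:
continuous variables are drawn from families parameterised by the printed
median and IQR and coupled through a Gaussian copula with user-specified
Spearman rank correlations; categorical variables are drawn at the printed
frequencies.  Cardiovascular comorbidity flags share a single latent factor
whose loading is solved so the composite "any CVD" prevalence matches its
printed value while the per-condition marginals are preserved.

All medians/IQRs here use the standard type-7 (linear-interpolation)
quantile definition.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError

__all__ = [
    "RISK_FACTORS",
    "RiskFactorVector",
    "BaselineProfile",
    "ContinuousMarginal",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "summarize_cohort",
    "hba1c_pct_to_mmolmol",
    "hba1c_mmolmol_to_pct",
    "default_cohort_spec",
]

#: The nine modelled risk factors, in canonical column order.  Lipids are
#: carried in mg/dL throughout (the US-unit convention of the risk engine).
RISK_FACTORS = (
    "hba1c",
    "bmi",
    "sbp",
    "dbp",
    "hdl",
    "ldl",
    "total_cholesterol",
    "triglycerides_nonfasting",
    "egfr",
)

SECOND_LINE_CLASSES = ("SU", "DPP4i", "SGLT2i")

HISTORY_FLAGS = ("angina", "mi", "stroke", "hf", "hypoglycaemia")
#: Flags whose union defines the composite baseline-CVD indicator.
CVD_COMPONENT_FLAGS = ("angina", "mi", "stroke", "hf")

# IFCC master equation relating NGSP (%) and IFCC (mmol/mol) HbA1c scales.
_IFCC_SLOPE = 10.929
_IFCC_OFFSET = 2.15

_NORM_Q75 = stats.norm.ppf(0.75)  # 0.6744897...


def hba1c_pct_to_mmolmol(value, rounded: bool = False):
    """Convert HbA1c from NGSP % to IFCC mmol/mol.

    mmol/mol = 10.929 x (% - 2.15).  With ``rounded=True`` the result is
    rounded to the nearest integer, the convention for display; the inverse
    conversion is exact on the un-rounded value.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("HbA1c (%) must be strictly positive")
    out = _IFCC_SLOPE * (arr - _IFCC_OFFSET)
    if rounded:
        out = np.rint(out)
    if np.isscalar(value):
        return float(out)
    return out


def hba1c_mmolmol_to_pct(value):
    """Inverse of :func:`hba1c_pct_to_mmolmol` (exact, un-rounded)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("HbA1c (mmol/mol) must be strictly positive")
    out = arr / _IFCC_SLOPE + _IFCC_OFFSET
    if np.isscalar(value):
        return float(out)
    return out


@dataclass(frozen=True)
class RiskFactorVector:
    """One individual's nine risk-factor levels.

    Units: hba1c %, bmi kg/m2, sbp/dbp mm Hg, lipids mg/dL,
    egfr mL/min/1.73m2.
    """

    hba1c: float
    bmi: float
    sbp: float
    dbp: float
    hdl: float
    ldl: float
    total_cholesterol: float
    triglycerides_nonfasting: float
    egfr: float

    def __post_init__(self):
        for name in RISK_FACTORS:
            if getattr(self, name) <= 0:
                raise ValueError(f"risk factor {name!r} must be strictly positive")
        if self.sbp <= self.dbp:
            raise ValueError("systolic pressure must exceed diastolic pressure")
        if self.total_cholesterol < self.hdl:
            raise ValueError("total cholesterol cannot be below HDL")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in RISK_FACTORS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RiskFactorVector":
        return cls(**dict(zip(RISK_FACTORS, map(float, values))))


@dataclass(frozen=True)
class BaselineProfile:
    """Pre-second-line state of one simulated individual."""

    id: str
    age: float
    sex: str
    ethnicity: str
    imd_quintile: str
    years_since_diagnosis: float
    risk_factors: RiskFactorVector
    history_flags: Mapping[str, bool]
    second_line_class: str

    def __post_init__(self):
        if self.age < 18:
            raise ValueError("cohort is adult: age must be >= 18")
        if self.years_since_diagnosis < 0:
            raise ValueError("years_since_diagnosis must be >= 0")
        if self.second_line_class not in SECOND_LINE_CLASSES:
            raise ValueError(f"unknown second-line class {self.second_line_class!r}")

    @property
    def cvd_history(self) -> bool:
        """Composite of angina/MI/stroke/heart-failure history."""
        return any(bool(self.history_flags[f]) for f in CVD_COMPONENT_FLAGS)


class ContinuousMarginal:
    """A one-dimensional marginal distribution solved from printed quantiles.

    Families:

    ``normal``
        location = median, scale = IQR width / (2 * z_0.75).
    ``lognormal``
        log-location = ln(median), log-scale = ln(q3/q1) / (2 * z_0.75),
        so the median and the quartile *ratio* are matched exactly.
    ``quantile_knots``
        piecewise-linear quantile function through arbitrary (p, q) knots;
        matches every supplied quantile exactly and accommodates shapes
        (e.g. left-skew inside the IQR) the two parametric families cannot.

    ``floor``/``ceil`` clip the sampled values; clipping at several sigma
    from the centre leaves the targeted quantiles untouched.
    """

    FAMILIES = ("normal", "lognormal", "quantile_knots")

    def __init__(self, family: str, params: Mapping[str, object],
                 floor: float | None = None, ceil: float | None = None):
        if family not in self.FAMILIES:
            raise ConfigurationError(f"unknown distribution family {family!r}")
        self.family = family
        self.params = dict(params)
        self.floor = floor
        self.ceil = ceil
        if family == "quantile_knots":
            knots = sorted((float(p), float(q)) for p, q in self.params["knots"])
            ps = [p for p, _ in knots]
            qs = [q for _, q in knots]
            if ps[0] > 0.0 or ps[-1] < 1.0:
                raise ConfigurationError("quantile knots must span p=0..1")
            if any(b < a for a, b in zip(qs, qs[1:])):
                raise ConfigurationError("quantile knots must be nondecreasing")
            self._knot_p = np.array(ps)
            self._knot_q = np.array(qs)

    @classmethod
    def from_quartiles(cls, family: str, q1: float, median: float, q3: float,
                       floor: float | None = None, ceil: float | None = None,
                       lo: float | None = None, hi: float | None = None):
        """Solve family parameters from the printed median and IQR."""
        if not (q1 <= median <= q3):
            raise ConfigurationError("require q1 <= median <= q3")
        if family == "normal":
            sigma = (q3 - q1) / (2 * _NORM_Q75)
            return cls("normal", {"mu": median, "sigma": sigma}, floor, ceil)
        if family == "lognormal":
            if q1 <= 0:
                raise ConfigurationError("lognormal requires positive quartiles")
            sigma = math.log(q3 / q1) / (2 * _NORM_Q75)
            return cls("lognormal", {"mu": math.log(median), "sigma": sigma},
                       floor, ceil)
        if family == "quantile_knots":
            if lo is None:
                lo = max(0.0, q1 - 1.5 * (q3 - q1))
            if hi is None:
                hi = q3 + 1.5 * (q3 - q1)
            knots = [(0.0, lo), (0.25, q1), (0.5, median), (0.75, q3), (1.0, hi)]
            return cls("quantile_knots", {"knots": knots}, floor, ceil)
        raise ConfigurationError(f"unknown distribution family {family!r}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.family == "normal":
            x = stats.norm.ppf(u, loc=self.params["mu"], scale=self.params["sigma"])
        elif self.family == "lognormal":
            x = np.exp(stats.norm.ppf(u, loc=self.params["mu"],
                                      scale=self.params["sigma"]))
        else:
            x = np.interp(u, self._knot_p, self._knot_q)
        if self.floor is not None:
            x = np.maximum(x, self.floor)
        if self.ceil is not None:
            x = np.minimum(x, self.ceil)
        return x

    def median(self) -> float:
        return float(self.ppf(np.array(0.5)))

    def mean(self) -> float:
        """Population mean (closed form per family; exact for the knots)."""
        if self.family == "normal":
            return float(self.params["mu"])
        if self.family == "lognormal":
            return float(math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2))
        # piecewise-linear quantile function: mean = integral of Q over [0,1],
        # trapezoid rule is exact on each linear piece
        return float(np.trapezoid(self._knot_q, self._knot_p))

    def to_dict(self) -> dict:
        params = {}
        for k, v in self.params.items():
            if k == "knots":
                params[k] = [[float(p), float(q)] for p, q in v]
            else:
                params[k] = float(v)
        d = {"family": self.family, "params": params}
        if self.floor is not None:
            d["floor"] = float(self.floor)
        if self.ceil is not None:
            d["ceil"] = float(self.ceil)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ContinuousMarginal":
        return cls(d["family"], d["params"], d.get("floor"), d.get("ceil"))


def _solve_shared_loading(probs: Sequence[float], target_any: float) -> float:
    """Loading rho of a single latent factor shared by binary flags such that
    P(any flag) equals ``target_any`` while marginal prevalences are kept.

    P(none) = E_L[ prod_j Phi((z_j - rho L)/sqrt(1-rho^2)) ] is evaluated by
    Gauss-Hermite quadrature and rho solved by bisection.
    """
    probs = np.asarray(probs, dtype=float)
    z = stats.norm.isf(probs)  # threshold: flag_j <=> latent_j > z_j
    indep_none = float(np.prod(1 - probs))
    target_none = 1.0 - target_any
    if target_none <= indep_none:  # independence already concentrates enough
        return 0.0
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    l = nodes * math.sqrt(2.0)
    w = weights / math.sqrt(math.pi)

    def p_none(rho):
        s = math.sqrt(1 - rho ** 2)
        cond = stats.norm.cdf((z[None, :] - rho * l[:, None]) / s)
        return float(w @ np.prod(cond, axis=1))

    return optimize.brentq(lambda r: p_none(r) - target_none, 0.0, 0.999,
                           xtol=1e-10)


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort.

    ``rank_corr`` holds target Spearman correlations among the nine risk
    factors (order of :data:`RISK_FACTORS`); age and diabetes duration are
    drawn independently of the copula.
    """

    n: int
    marginals: Mapping[str, ContinuousMarginal]
    rank_corr: np.ndarray
    sex: Mapping[str, float]
    ethnicity: Mapping[str, float]
    imd_quintile: Mapping[str, float]
    second_line: Mapping[str, float]
    comorbidity: Mapping[str, float]
    cvd_composite_target: float | None = None

    def __post_init__(self):
        self.rank_corr = np.asarray(self.rank_corr, dtype=float)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size n must be >= 1")
        needed = set(RISK_FACTORS) | {"age", "years_since_diagnosis"}
        missing = needed - set(self.marginals)
        if missing:
            raise ConfigurationError(f"missing marginals: {sorted(missing)}")
        k = len(RISK_FACTORS)
        R = self.rank_corr
        if R.shape != (k, k):
            raise ConfigurationError(f"rank_corr must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigurationError("rank_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("rank_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(self._pearson_corr())) < -1e-10:
            raise ConfigurationError("rank correlation matrix is not positive "
                                     "semi-definite under the Gaussian copula")
        for name, freqs in [("sex", self.sex), ("ethnicity", self.ethnicity),
                            ("imd_quintile", self.imd_quintile),
                            ("second_line", self.second_line)]:
            total = sum(freqs.values())
            # printed percentages may carry rounding error (e.g. an IMD
            # column summing to 100.1%); frequencies are renormalised at
            # sampling time
            if abs(total - 1.0) > 5e-3:
                raise ConfigurationError(
                    f"{name} category frequencies sum to {total}, not 1")
        for flag, p in self.comorbidity.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"comorbidity prevalence {flag}={p}")

    def _pearson_corr(self) -> np.ndarray:
        """Pearson correlation of the latent normals reproducing the target
        Spearman correlations under a Gaussian copula: r = 2 sin(pi rho / 6)."""
        return 2.0 * np.sin(np.pi * self.rank_corr / 6.0)

    def continuous_means(self) -> dict:
        return {name: m.mean() for name, m in self.marginals.items()}

    def covariate_means(self) -> dict:
        """Population means of the covariates entering the engines."""
        return {
            "age": self.marginals["age"].mean(),
            "sex_female": self.sex.get("female", 0.0),
            "years_since_diagnosis": self.marginals["years_since_diagnosis"].mean(),
            "cvd_history": (self.cvd_composite_target
                            if self.cvd_composite_target is not None
                            else 1 - np.prod([1 - self.comorbidity[f]
                                              for f in CVD_COMPONENT_FLAGS])),
        }

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "marginals": {k: v.to_dict() for k, v in self.marginals.items()},
            "rank_corr": np.asarray(self.rank_corr).tolist(),
            "sex": dict(self.sex),
            "ethnicity": dict(self.ethnicity),
            "imd_quintile": dict(self.imd_quintile),
            "second_line": dict(self.second_line),
            "comorbidity": dict(self.comorbidity),
            "cvd_composite_target": self.cvd_composite_target,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        return cls(
            n=int(d["n"]),
            marginals={k: ContinuousMarginal.from_dict(v)
                       for k, v in d["marginals"].items()},
            rank_corr=np.asarray(d["rank_corr"], dtype=float),
            sex=dict(d["sex"]),
            ethnicity=dict(d["ethnicity"]),
            imd_quintile=dict(d["imd_quintile"]),
            second_line=dict(d["second_line"]),
            comorbidity=dict(d["comorbidity"]),
            cvd_composite_target=d.get("cvd_composite_target"),
        )


class Cohort:
    """A generated cohort: a DataFrame (one row per individual) that also
    iterates as :class:`BaselineProfile` objects."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[BaselineProfile]:
        for _, row in self.frame.iterrows():
            yield self.profile_from_row(row)

    def __getitem__(self, i: int) -> BaselineProfile:
        return self.profile_from_row(self.frame.iloc[i])

    @staticmethod
    def profile_from_row(row: pd.Series) -> BaselineProfile:
        return BaselineProfile(
            id=str(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            ethnicity=str(row["ethnicity"]),
            imd_quintile=str(row["imd_quintile"]),
            years_since_diagnosis=float(row["years_since_diagnosis"]),
            risk_factors=RiskFactorVector.from_array(
                [row[f] for f in RISK_FACTORS]),
            history_flags={f: bool(row[f"history_{f}"]) for f in HISTORY_FLAGS},
            second_line_class=str(row["second_line_class"]),
        )

    def risk_factor_matrix(self) -> np.ndarray:
        return self.frame[list(RISK_FACTORS)].to_numpy(dtype=float)

    def covariate_matrix(self) -> pd.DataFrame:
        """Engine covariates: age, sex_female, years_since_diagnosis,
        cvd_history (floats)."""
        f = self.frame
        return pd.DataFrame({
            "age": f["age"].astype(float),
            "sex_female": (f["sex"] == "female").astype(float),
            "years_since_diagnosis": f["years_since_diagnosis"].astype(float),
            "cvd_history": f["cvd_history"].astype(float),
        }, index=f.index)


def _sample_categorical(rng: np.random.Generator, freqs: Mapping[str, float],
                        n: int) -> np.ndarray:
    levels = list(freqs.keys())
    p = np.array([freqs[k] for k in levels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(levels), size=n, p=p)
    return np.array(levels, dtype=object)[idx]


def generate_cohort(spec: CohortSpec, seed: int, n: int | None = None) -> Cohort:
    """Draw a cohort of ``n`` individuals (default ``spec.n``).

    Deterministic for a fixed (spec, seed): the order of RNG consumption is
    part of the contract.  Continuous risk factors are coupled by a Gaussian
    copula at the spec's rank correlations; age, diabetes duration,
    categorical descriptors and the treatment arm are drawn independently.
    """
    spec.validate()
    n = int(spec.n if n is None else n)
    if n < 1:
        raise ConfigurationError("cohort size n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1C0]))

    # 1. copula-coupled risk factors
    pearson = spec._pearson_corr()
    try:
        chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(len(RISK_FACTORS)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught by validate
        raise ConfigurationError("correlation matrix is not PSD") from exc
    z = rng.standard_normal((n, len(RISK_FACTORS))) @ chol.T
    u = stats.norm.cdf(z)
    X = np.column_stack([spec.marginals[f].ppf(u[:, j])
                         for j, f in enumerate(RISK_FACTORS)])
    frame = pd.DataFrame(X, columns=list(RISK_FACTORS))

    # physiologic consistency repairs (rare tail events; counted)
    bad_bp = frame["sbp"] <= frame["dbp"]
    frame.loc[bad_bp, "sbp"] = frame.loc[bad_bp, "dbp"] + 5.0
    bad_tc = frame["total_cholesterol"] < frame["hdl"]
    frame.loc[bad_tc, "total_cholesterol"] = frame.loc[bad_tc, "hdl"]
    repairs = int(bad_bp.sum() + bad_tc.sum())

    # 2. demographics
    frame.insert(0, "id", [f"ind{i:06d}" for i in range(n)])
    frame["age"] = spec.marginals["age"].ppf(rng.random(n))
    frame["years_since_diagnosis"] = \
        spec.marginals["years_since_diagnosis"].ppf(rng.random(n))
    frame["sex"] = _sample_categorical(rng, spec.sex, n)
    frame["ethnicity"] = _sample_categorical(rng, spec.ethnicity, n)
    frame["imd_quintile"] = _sample_categorical(rng, spec.imd_quintile, n)

    # 3. comorbidity flags with a shared latent factor for the CVD composite
    rho = 0.0
    if spec.cvd_composite_target is not None:
        rho = _solve_shared_loading(
            [spec.comorbidity[f] for f in CVD_COMPONENT_FLAGS],
            spec.cvd_composite_target)
    latent = rng.standard_normal(n)
    s = math.sqrt(1 - rho ** 2)
    for flag in HISTORY_FLAGS:
        p = spec.comorbidity[flag]
        thresh = stats.norm.isf(p)
        if flag in CVD_COMPONENT_FLAGS:
            val = rho * latent + s * rng.standard_normal(n)
        else:
            val = rng.standard_normal(n)
        frame[f"history_{flag}"] = val > thresh
    frame["cvd_history"] = np.logical_or.reduce(
        [frame[f"history_{f}"].to_numpy() for f in CVD_COMPONENT_FLAGS])

    # 4. treatment arm
    frame["second_line_class"] = _sample_categorical(rng, spec.second_line, n)

    frame.attrs["repairs"] = repairs
    frame.attrs["cvd_latent_loading"] = rho
    return Cohort(frame)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Summary table: median/IQR per continuous variable, count/% per
    category level.  Raises on an empty cohort."""
    f = cohort.frame if isinstance(cohort, Cohort) else cohort
    if len(f) == 0:
        raise ValueError("cannot summarise an empty cohort")
    n = len(f)
    rows = []
    for var in ["age", "years_since_diagnosis", *RISK_FACTORS]:
        q1, med, q3 = np.quantile(f[var].to_numpy(dtype=float),
                                  [0.25, 0.5, 0.75])
        rows.append({"variable": var, "level": "", "median": med,
                     "q1": q1, "q3": q3, "count": np.nan, "percent": np.nan})
    # display companion row on the IFCC scale
    hq1, hmed, hq3 = (hba1c_pct_to_mmolmol(
        np.quantile(f["hba1c"].to_numpy(dtype=float), [0.25, 0.5, 0.75]),
        rounded=True))
    rows.append({"variable": "hba1c_mmolmol", "level": "", "median": hmed,
                 "q1": hq1, "q3": hq3, "count": np.nan, "percent": np.nan})
    for var in ["sex", "ethnicity", "imd_quintile", "second_line_class"]:
        for level, count in f[var].value_counts().items():
            rows.append({"variable": var, "level": str(level), "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "count": int(count),
                         "percent": 100.0 * count / n})
    for flag in [*HISTORY_FLAGS]:
        count = int(f[f"history_{flag}"].sum())
        rows.append({"variable": f"history_{flag}", "level": "True",
                     "median": np.nan, "q1": np.nan, "q3": np.nan,
                     "count": count, "percent": 100.0 * count / n})
    count = int(f["cvd_history"].sum())
    rows.append({"variable": "cvd_history", "level": "True", "median": np.nan,
                 "q1": np.nan, "q3": np.nan, "count": count,
                 "percent": 100.0 * count / n})
    return pd.DataFrame(rows)


def default_rank_corr() -> np.ndarray:
    """Weak, clinically plausible Spearman structure among the risk factors
    (BMI-blood pressure, LDL-total cholesterol, triglycerides-HDL...).
    The matrix is user-overridable; identity is always valid."""
    k = len(RISK_FACTORS)
    idx = {name: i for i, name in enumerate(RISK_FACTORS)}
    R = np.eye(k)

    def put(a, b, v):
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = v

    put("bmi", "sbp", 0.20)
    put("bmi", "dbp", 0.15)
    put("sbp", "dbp", 0.50)
    put("ldl", "total_cholesterol", 0.80)
    put("hdl", "total_cholesterol", 0.20)
    put("triglycerides_nonfasting", "total_cholesterol", 0.30)
    put("triglycerides_nonfasting", "ldl", 0.20)
    put("triglycerides_nonfasting", "hdl", -0.25)
    put("triglycerides_nonfasting", "bmi", 0.20)
    put("hba1c", "triglycerides_nonfasting", 0.10)
    put("egfr", "sbp", -0.10)
    return R


def default_cohort_spec(n: int = 62_640) -> CohortSpec:
    """Cohort spec calibrated to the published baseline-characteristics table
    of the England second-line treatment population (n = 62,640).

    Family choices: log-normal where the median sits off-centre in the IQR
    (BMI, triglycerides, HbA1c), normal elsewhere; diabetes duration uses the
    quantile-knot family because its printed quartiles (2.5, 4.9, 5.0) are
    left-skewed inside the IQR beyond what either parametric family can fit.
    """
    m = {
        "age": ContinuousMarginal.from_quartiles(
            "normal", 52.0, 60.0, 69.0, floor=18.0),
        "years_since_diagnosis": ContinuousMarginal.from_quartiles(
            "quantile_knots", 2.5, 4.9, 5.0, lo=0.0, hi=15.0, floor=0.0),
        "hba1c": ContinuousMarginal.from_quartiles(
            "lognormal", 7.3, 7.9, 8.8, floor=4.0),
        "bmi": ContinuousMarginal.from_quartiles(
            "lognormal", 28.0, 31.3, 36.0, floor=15.0),
        "sbp": ContinuousMarginal.from_quartiles(
            "normal", 124.0, 132.0, 140.0, floor=80.0),
        "dbp": ContinuousMarginal.from_quartiles(
            "normal", 73.0, 79.0, 82.0, floor=40.0),
        "hdl": ContinuousMarginal.from_quartiles(
            "normal", 38.7, 42.5, 50.3, floor=15.0),
        "ldl": ContinuousMarginal.from_quartiles(
            "normal", 61.9, 81.2, 104.4, floor=20.0),
        "total_cholesterol": ContinuousMarginal.from_quartiles(
            "normal", 139.2, 158.5, 185.6, floor=60.0),
        "triglycerides_nonfasting": ContinuousMarginal.from_quartiles(
            "lognormal", 115.1, 159.4, 221.4, floor=30.0),
        "egfr": ContinuousMarginal.from_quartiles(
            "normal", 80.0, 92.0, 102.0, floor=5.0),
    }
    return CohortSpec(
        n=n,
        marginals=m,
        rank_corr=default_rank_corr(),
        sex={"female": 0.394, "male": 0.606},
        ethnicity={"White": 0.725, "Black": 0.050, "Other": 0.225},
        imd_quintile={"1": 0.142, "2": 0.177, "3": 0.181, "4": 0.219,
                      "5": 0.232, "missing": 0.050},
        second_line={"SU": 0.490, "DPP4i": 0.408, "SGLT2i": 0.102},
        comorbidity={"angina": 0.033, "mi": 0.061, "stroke": 0.042,
                     "hf": 0.047, "hypoglycaemia": 0.008},
        cvd_composite_target=0.138,
    )
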