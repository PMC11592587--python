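"""Synthetic biopsy-staged MASLD cohorts with T2DM and fibrosis strata.

No patient-level data accompany the published index, only group-level
baseline tables: per-stratum means and standard deviations of the
laboratory variables, stratum prevalences, and the fibrosis-stage
breakdown. This module generates virtual cohorts that reproduce those
first and second moments exactly in expectation, so that every analysis
module in the package can be exercised end to end without any download.

Design of the generator
-----------------------
* A patient belongs to one of four strata — T2DM x advanced fibrosis
  (stage >= F3) — drawn i.i.d. with the published prevalences (34.4%
  T2DM; advanced fibrosis in 30.0% of T2DM and 13.2% of non-T2DM
  patients). Per-class laboratory moments are published only for the
  T2DM strata; the two non-T2DM strata share the non-T2DM marginals.
* Each continuous variable is a truncated normal whose underlying
  location/scale are solved numerically so that the *truncated*
  distribution has the published mean and SD (plain truncation at a
  physiologic lower bound would bias means of skewed labs such as ALT by
  several standard errors). A lognormal family is available per variable.
* Within a stratum, variables are coupled by a Gaussian copula. The
  published tables carry no correlations; the defaults (AST-ALT 0.7,
  AST-age 0.1, platelets-age -0.2, all else 0) are artifact assumptions,
  fully configurable, and do not affect marginal moments.
* Glucose, HbA1c and the medication flag are sampled consistently with
  the stratum's T2DM status: non-T2DM strata draw glucose and HbA1c from
  moment-matched distributions truncated below the diagnostic thresholds
  (fasting glucose 126 mg/dL, HbA1c 6.5%), and any T2DM record that
  happens to fail all three diagnostic criteria has its medication flag
  set. The diabetes label recomputed from the record therefore always
  agrees with the generating stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import Cohort, PatientRecord, label_t2dm
from .errors import ValidationError

#: Copula variable order within every stratum.
CONTINUOUS_VARIABLES = ("age", "bmi", "waist", "platelets", "ast", "alt",
                        "albumin", "triglycerides", "hdl", "ldl", "glucose",
                        "hba1c")

_FAMILIES = ("truncnorm", "lognormal")


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one continuous variable in one stratum."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf
    family: str = "truncnorm"

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise ValidationError(f"{name}: sd must be > 0")
        if not self.lower < self.upper:
            raise ValidationError(f"{name}: lower must be < upper")
        if self.family not in _FAMILIES:
            raise ValidationError(f"{name}: unknown family {self.family!r}")


@dataclass
class StratumSpec:
    """One generation stratum: membership probability, stage mix, marginal
    distributions, and binary-field probabilities."""

    name: str
    probability: float
    t2dm: bool
    stage_probs: dict[int, float]
    variables: dict[str, VariableSpec]
    p_male: float
    p_hypertension: float
    p_diabetes_meds: float

    def validate(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"{self.name}: probability out of [0,1]")
        tot = sum(self.stage_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"{self.name}: stage probabilities sum to {tot}")
        for s in self.stage_probs:
            if s not in (0, 1, 2, 3, 4):
                raise ValidationError(f"{self.name}: invalid stage {s}")
        for p in (self.p_male, self.p_hypertension, self.p_diabetes_meds):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{self.name}: binary probability out of [0,1]")
        for v in CONTINUOUS_VARIABLES:
            if v not in self.variables:
                raise ValidationError(f"{self.name}: missing variable {v!r}")
            self.variables[v].validate(f"{self.name}.{v}")


@dataclass
class CohortSpec:
    """Full generative specification of a virtual cohort."""

    strata: list[StratumSpec]
    #: correlations applied through a Gaussian copula, keyed by sorted
    #: variable-name pairs; unlisted pairs are independent.
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    #: scale parameter (g/week) of the truncated-exponential alcohol draw
    alcohol_scale: float = 30.0

    def validate(self) -> None:
        if not self.strata:
            raise ValidationError("spec has no strata")
        tot = sum(s.probability for s in self.strata)
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"stratum probabilities sum to {tot}")
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate stratum names")
        for s in self.strata:
            s.validate()
        R = self.correlation_matrix()
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ValidationError("correlation matrix is not positive semi-definite")

    def correlation_matrix(self) -> np.ndarray:
        k = len(CONTINUOUS_VARIABLES)
        idx = {v: i for i, v in enumerate(CONTINUOUS_VARIABLES)}
        R = np.eye(k)
        for (a, b), rho in self.correlations.items():
            if a not in idx or b not in idx:
                raise ValidationError(f"unknown variable in correlation pair ({a},{b})")
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"correlation {rho} out of (-1,1)")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        return R

    # -- text serialization (YAML) ------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "alcohol_scale": self.alcohol_scale,
            "correlations": [{"pair": list(k), "rho": v}
                             for k, v in sorted(self.correlations.items())],
            "strata": [
                {**{k: v for k, v in asdict(s).items()
                    if k not in ("variables", "stage_probs")},
                 "stage_probs": {int(k): float(v)
                                 for k, v in s.stage_probs.items()},
                 "variables": {n: asdict(vs) for n, vs in s.variables.items()}}
                for s in self.strata],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        strata = []
        for s in doc["strata"]:
            strata.append(StratumSpec(
                name=s["name"], probability=s["probability"], t2dm=s["t2dm"],
                stage_probs={int(k): float(v) for k, v in s["stage_probs"].items()},
                variables={n: VariableSpec(**vs)
                           for n, vs in s["variables"].items()},
                p_male=s["p_male"], p_hypertension=s["p_hypertension"],
                p_diabetes_meds=s["p_diabetes_meds"]))
        corr = {tuple(e["pair"]): float(e["rho"])
                for e in doc.get("correlations", [])}
        spec = cls(strata=strata, correlations=corr,
                   alcohol_scale=float(doc.get("alcohol_scale", 30.0)))
        spec.validate()
        return spec


# -- published baseline tables, transcribed --------------------------------

def _v(mean, sd, lower, upper=math.inf):
    return VariableSpec(mean=mean, sd=sd, lower=lower, upper=upper)


_GLUCOSE_T2DM_CAP = 126.0  # fasting threshold; non-T2DM stays below
_HBA1C_CAP = 6.5

# physiologic lower bounds (same across strata)
_LO = dict(age=19.0, bmi=12.0, waist=40.0, platelets=10.0, ast=5.0, alt=5.0,
           albumin=1.5, triglycerides=20.0, hdl=10.0, ldl=20.0, glucose=40.0,
           hba1c=3.5)


def default_spec() -> CohortSpec:
    """The packaged specification transcribing the published baseline
    tables: per-stratum means +/- SDs for the T2DM advanced (>=F3) and
    F0-2 classes, non-T2DM marginals, 34.4% T2DM prevalence, advanced
    fibrosis in 30.0% (T2DM) and 13.2% (non-T2DM), and the printed
    F3:F4 = 112:43 and F0/1:F2 = 228:134 stage splits (F0/1 divided
    evenly). HbA1c and medication rates are not published; clinically
    typical defaults are used.
    """
    p_t2dm = 517.0 / 1503.0
    p_adv_t2dm = 0.30
    p_adv_non = 0.132

    t2dm_adv_vars = {
        "age": _v(57.5, 12.2, _LO["age"]),
        "bmi": _v(29.41, 4.48, _LO["bmi"]),
        "waist": _v(98.28, 7.75, _LO["waist"]),
        "platelets": _v(183.91, 73.51, _LO["platelets"]),
        "ast": _v(65.35, 33.84, _LO["ast"]),
        "alt": _v(75.90, 47.52, _LO["alt"]),
        "albumin": _v(4.20, 0.47, _LO["albumin"]),
        "triglycerides": _v(141.09, 64.46, _LO["triglycerides"]),
        "hdl": _v(47.60, 17.15, _LO["hdl"]),
        "ldl": _v(122.30, 82.12, _LO["ldl"]),
        "glucose": _v(142.56, 46.87, _LO["glucose"]),
        "hba1c": _v(7.3, 1.3, _LO["hba1c"]),
    }
    t2dm_f02_vars = {
        "age": _v(52.2, 12.9, _LO["age"]),
        "bmi": _v(29.33, 5.43, _LO["bmi"]),
        "waist": _v(95.90, 14.99, _LO["waist"]),
        "platelets": _v(232.279, 68.52, _LO["platelets"]),
        "ast": _v(55.99, 38.10, _LO["ast"]),
        "alt": _v(79.31, 59.39, _LO["alt"]),
        "albumin": _v(4.32, 0.45, _LO["albumin"]),
        "triglycerides": _v(175.49, 106.39, _LO["triglycerides"]),
        "hdl": _v(45.68, 13.92, _LO["hdl"]),
        "ldl": _v(116.31, 38.01, _LO["ldl"]),
        "glucose": _v(140.91, 44.34, _LO["glucose"]),
        "hba1c": _v(7.3, 1.3, _LO["hba1c"]),
    }
    non_vars = {
        "age": _v(45.11, 14.95, _LO["age"]),
        "bmi": _v(29.41, 7.23, _LO["bmi"]),
        "waist": _v(95.41, 11.75, _LO["waist"]),
        "platelets": _v(246.55, 70.32, _LO["platelets"]),
        "ast": _v(47.74, 33.87, _LO["ast"]),
        "alt": _v(71.19, 60.20, _LO["alt"]),
        "albumin": _v(4.35, 0.42, _LO["albumin"]),
        "triglycerides": _v(156.62, 102.69, _LO["triglycerides"]),
        "hdl": _v(49.00, 14.56, _LO["hdl"]),
        "ldl": _v(127.54, 47.84, _LO["ldl"]),
        "glucose": _v(99.45, 16.10, _LO["glucose"], _GLUCOSE_T2DM_CAP),
        "hba1c": _v(5.5, 0.4, _LO["hba1c"], _HBA1C_CAP),
    }

    adv_stages = {3: 112.0 / 155.0, 4: 43.0 / 155.0}
    f02_stages = {0: 114.0 / 362.0, 1: 114.0 / 362.0, 2: 134.0 / 362.0}

    strata = [
        StratumSpec("t2dm_advanced", p_t2dm * p_adv_t2dm, True, adv_stages,
                    t2dm_adv_vars, p_male=0.419, p_hypertension=0.658,
                    p_diabetes_meds=0.70),
        StratumSpec("t2dm_f0_2", p_t2dm * (1 - p_adv_t2dm), True, f02_stages,
                    t2dm_f02_vars, p_male=0.486, p_hypertension=0.554,
                    p_diabetes_meds=0.70),
        StratumSpec("non_t2dm_advanced", (1 - p_t2dm) * p_adv_non, False,
                    adv_stages, non_vars, p_male=0.493, p_hypertension=0.339,
                    p_diabetes_meds=0.0),
        StratumSpec("non_t2dm_f0_2", (1 - p_t2dm) * (1 - p_adv_non), False,
                    f02_stages, non_vars, p_male=0.493, p_hypertension=0.339,
                    p_diabetes_meds=0.0),
    ]
    spec = CohortSpec(
        strata=strata,
        correlations={("alt", "ast"): 0.7, ("age", "ast"): 0.1,
                      ("age", "platelets"): -0.2},
    )
    spec.validate()
    return spec


# -- moment-matched truncated marginals -------------------------------------

_match_cache: dict[tuple, tuple[float, float]] = {}


def _truncnorm_ab(mu, sigma, lower, upper):
    return (lower - mu) / sigma, (upper - mu) / sigma


def _match_truncnorm(mean, sd, lower, upper) -> tuple[float, float]:
    """Underlying (mu, sigma) whose (lower, upper)-truncated normal has
    the requested mean and SD."""
    key = (round(mean, 10), round(sd, 10), lower, upper)
    if key in _match_cache:
        return _match_cache[key]

    def resid(p):
        mu, logs = p
        s = math.exp(logs)
        a, b = _truncnorm_ab(mu, s, lower, upper)
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.least_squares(resid, [mean, math.log(sd)],
                                 xtol=1e-13, ftol=1e-13, gtol=1e-13)
    if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(1.0, sd):
        raise ValidationError(
            f"cannot moment-match truncated normal to mean={mean}, sd={sd} "
            f"on ({lower}, {upper})")
    out = (float(sol.x[0]), float(math.exp(sol.x[1])))
    _match_cache[key] = out
    return out


def _marginal_ppf(vs: VariableSpec, u: np.ndarray) -> np.ndarray:
    """Quantile transform for one marginal, honoring truncation bounds."""
    if vs.family == "truncnorm":
        mu, sigma = _match_truncnorm(vs.mean, vs.sd, vs.lower, vs.upper)
        a, b = _truncnorm_ab(mu, sigma, vs.lower, vs.upper)
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    # lognormal: closed-form moment match of the untruncated law, then
    # quantile-mapped into the truncation window
    sigma2 = math.log(1.0 + (vs.sd / vs.mean) ** 2)
    s = math.sqrt(sigma2)
    scale = vs.mean * math.exp(-sigma2 / 2.0)
    dist = stats.lognorm(s=s, scale=scale)
    flo = dist.cdf(max(vs.lower, 0.0))
    fhi = dist.cdf(vs.upper) if math.isfinite(vs.upper) else 1.0
    return dist.ppf(flo + u * (fhi - flo))


# -- generation --------------------------------------------------------------

def _alcohol(rng, sex: np.ndarray, scale: float) -> np.ndarray:
    """Weekly ethanol grams, truncated exponential kept strictly below the
    MASLD limit for each sex (with a small margin)."""
    cap = np.where(sex, 205.0, 135.0)  # male 210, female 140, minus margin
    u = rng.random(sex.size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-cap / scale)))


def simulate(spec: CohortSpec, n: int, seed: int) -> Cohort:
    """Draw a cohort of *n* virtual patients from *spec*.

    Stratum-first: each record's stratum is drawn i.i.d. with the spec
    probabilities, then its variables from the stratum's copula-coupled
    marginals. Deterministic under *seed*; every record satisfies the
    patient-record invariants and the MASLD eligibility rules.
    """
    spec.validate()
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return Cohort([], provenance=f"synthetic(seed={seed}, n=0)")

    probs = np.array([s.probability for s in spec.strata])
    sizes = rng.multinomial(n, probs)
    L = np.linalg.cholesky(
        spec.correlation_matrix() + 1e-12 * np.eye(len(CONTINUOUS_VARIABLES)))

    records: list[PatientRecord] = []
    serial = 0
    for stratum, n_s in zip(spec.strata, sizes):
        if n_s == 0:
            continue
        z = rng.standard_normal((n_s, len(CONTINUOUS_VARIABLES))) @ L.T
        u = stats.norm.cdf(z)
        cols = {v: _marginal_ppf(stratum.variables[v], u[:, i])
                for i, v in enumerate(CONTINUOUS_VARIABLES)}
        male = rng.random(n_s) < stratum.p_male
        htn = rng.random(n_s) < stratum.p_hypertension
        meds = rng.random(n_s) < stratum.p_diabetes_meds
        stages = rng.choice(sorted(stratum.stage_probs),
                            p=[stratum.stage_probs[k]
                               for k in sorted(stratum.stage_probs)],
                            size=n_s)
        alcohol = _alcohol(rng, male, spec.alcohol_scale)
        if stratum.t2dm:
            # any draw failing all three diagnostic criteria gets the
            # medication flag, keeping the label consistent by construction
            discordant = (~meds & (cols["glucose"] < 126.0)
                          & (cols["hba1c"] <= 6.5))
            meds = meds | discordant
        for i in range(n_s):
            serial += 1
            records.append(PatientRecord(
                id=f"P{serial:06d}",
                age=float(cols["age"][i]),
                sex="male" if male[i] else "female",
                bmi=float(cols["bmi"][i]),
                waist=float(cols["waist"][i]),
                platelets=float(cols["platelets"][i]),
                ast=float(cols["ast"][i]),
                alt=float(cols["alt"][i]),
                albumin=float(cols["albumin"][i]),
                triglycerides=float(cols["triglycerides"][i]),
                hdl=float(cols["hdl"][i]),
                ldl=float(cols["ldl"][i]),
                glucose=float(cols["glucose"][i]),
                hba1c=float(cols["hba1c"][i]),
                hypertension=bool(htn[i]),
                on_diabetes_meds=bool(meds[i]),
                alcohol_g_per_week=float(alcohol[i]),
                fibrosis_stage=int(stages[i]),
            ))
    return Cohort(records, provenance=f"synthetic(seed={seed}, n={n})")


# -- generation validation ----------------------------------------------------

@dataclass
class GenerationReport:
    """Realized-vs-specified moments, standardized by the sampling SE."""

    realized_sizes: dict[str, int]
    table: pd.DataFrame          # stratum, variable, spec/realized moments, z
    flags: list[str]             # "stratum.variable" with |z| > 4
    max_abs_z: Optional[float]


def _stratum_of(record: PatientRecord, spec: CohortSpec) -> Optional[str]:
    is_t2dm = label_t2dm(record)
    adv = record.fibrosis_stage is not None and record.fibrosis_stage >= 3
    for s in spec.strata:
        s_adv = all(k >= 3 for k in s.stage_probs)
        if s.t2dm == is_t2dm and s_adv == adv:
            return s.name
    return None


def validate_generation(c: Cohort, spec: CohortSpec) -> GenerationReport:
    """Compare realized per-stratum moments with the specification.

    For each stratum and variable the report carries the standardized
    deviation z = (realized mean - spec mean) / (spec sd / sqrt(n));
    |z| > 4 is flagged. An empty cohort yields a report with absent
    moments and no flags.
    """
    groups: dict[str, list[PatientRecord]] = {s.name: [] for s in spec.strata}
    for r in c:
        name = _stratum_of(r, spec)
        if name is not None:
            groups[name].append(r)
    rows, flags = [], []
    for s in spec.strata:
        recs = groups[s.name]
        n_s = len(recs)
        for v in CONTINUOUS_VARIABLES:
            vs = s.variables[v]
            if n_s == 0:
                rows.append({"stratum": s.name, "variable": v, "n": 0,
                             "spec_mean": vs.mean, "spec_sd": vs.sd,
                             "realized_mean": np.nan, "realized_sd": np.nan,
                             "z": np.nan})
                continue
            vals = np.array([getattr(r, v) for r in recs], float)
            z = (vals.mean() - vs.mean) / (vs.sd / math.sqrt(n_s))
            rows.append({"stratum": s.name, "variable": v, "n": n_s,
                         "spec_mean": vs.mean, "spec_sd": vs.sd,
                         "realized_mean": float(vals.mean()),
                         "realized_sd": float(vals.std(ddof=1)) if n_s > 1
                         else np.nan,
                         "z": float(z)})
            if abs(z) > 4.0:
                flags.append(f"{s.name}.{v}")
    table = pd.DataFrame(rows)
    zs = table["z"].dropna()
    return GenerationReport(
        realized_sizes={name: len(recs) for name, recs in groups.items()},
        table=table, flags=flags,
        max_abs_z=float(zs.abs().max()) if len(zs) else None)
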