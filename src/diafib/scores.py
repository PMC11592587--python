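"""FIB-4, the Diabetes Fibrosis Index, and the factored-quadratic score family.

The Diabetes Fibrosis Index (DFI) is a five-variable non-linear index for
screening advanced hepatic fibrosis (biopsy stage >= F3) in patients with
type 2 diabetes and MASLD:

    DFI = 1.4013*Age - 2.9859*Plt*(1 - 0.00159*Plt)
        + 5.8155*AST*(1 - 0.00365*AST) - 1.2014*ALT
        + 56.7468*BMI*(1 - 0.01467*BMI)

with platelets in 10^9/L, transaminases in IU/L, BMI in kg/m^2, and a
published screening cut-off of 715 (score >= 715 is at-risk). Each
non-linear term has the factored form a*X*(1 - c*X): a concave-down
parabola through the origin whose contribution peaks at X = 1/(2c), so
the index rewards mid-range platelet counts, AST, and BMI rather than
growing without bound. FIB-4 is the classical comparator:

    FIB-4 = (Age * AST) / (Plt * sqrt(ALT))

with the conventional rule-out cut-off of 1.3.

:class:`ScoreModel` generalizes the DFI to arbitrary coefficients of the
same family; the genetic-algorithm fitter in :mod:`diafib.ga` searches
this space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .cohort import Cohort
from .errors import ConfigError, DomainError, MissingDataError, ValidationError

#: Variables entering the factored-quadratic family, in gene order.
MODEL_VARIABLES = ("age", "platelets", "ast", "alt", "bmi")


@dataclass(frozen=True)
class FactoredTerm:
    """One non-linear term a*X*(1 - c*X); curvature c must be >= 0."""

    amplitude: float
    curvature: float

    def __post_init__(self):
        if self.curvature < 0:
            raise ValidationError(f"curvature must be >= 0, got {self.curvature}")

    def __call__(self, x):
        return self.amplitude * x * (1.0 - self.curvature * x)

    @property
    def peak(self) -> Optional[float]:
        """Location X = 1/(2c) where the term's derivative vanishes."""
        return None if self.curvature == 0 else 1.0 / (2.0 * self.curvature)


@dataclass(frozen=True)
class ScoreModel:
    """Coefficients of one member of the factored-quadratic score family.

    Linear in age and ALT; factored-quadratic in platelets, AST, and BMI.
    The published DFI is the fixed instance :data:`DFI_MODEL`.
    """

    name: str
    theta_age: float
    platelets: FactoredTerm
    ast: FactoredTerm
    theta_alt: float
    bmi: FactoredTerm
    cutoff: Optional[float] = None

    def score(self, age, platelets, ast, alt, bmi):
        """Evaluate the index; accepts scalars or numpy arrays."""
        return (self.theta_age * age
                + self.platelets(platelets)
                + self.ast(ast)
                + self.theta_alt * alt
                + self.bmi(bmi))

    def genes(self) -> np.ndarray:
        """Flatten to the 8-gene vector used by the GA:
        (theta_age, a_plt, c_plt, a_ast, c_ast, theta_alt, a_bmi, c_bmi)."""
        return np.array([
            self.theta_age,
            self.platelets.amplitude, self.platelets.curvature,
            self.ast.amplitude, self.ast.curvature,
            self.theta_alt,
            self.bmi.amplitude, self.bmi.curvature,
        ])

    @classmethod
    def from_genes(cls, genes, name="candidate", cutoff=None) -> "ScoreModel":
        g = np.asarray(genes, dtype=float)
        if g.shape != (8,):
            raise ValidationError(f"expected 8 genes, got shape {g.shape}")
        return cls(name, float(g[0]), FactoredTerm(float(g[1]), float(g[2])),
                   FactoredTerm(float(g[3]), float(g[4])), float(g[5]),
                   FactoredTerm(float(g[6]), float(g[7])), cutoff)


#: The published Diabetes Fibrosis Index with its screening cut-off.
DFI_MODEL = ScoreModel(
    name="dfi",
    theta_age=1.4013,
    platelets=FactoredTerm(-2.9859, 0.00159),
    ast=FactoredTerm(5.8155, 0.00365),
    theta_alt=-1.2014,
    bmi=FactoredTerm(56.7468, 0.01467),
    cutoff=715.0,
)

#: Conventional FIB-4 rule-out cut-off.
FIB4_CUTOFF = 1.3


def fib4(age, ast, alt, platelets):
    """FIB-4 index: (age * AST) / (platelets * sqrt(ALT)).

    Strictly increasing in age and AST, strictly decreasing in platelets
    and ALT; homogeneous of degree -1 in platelets. Raises
    :class:`~diafib.errors.DomainError` on non-positive arguments.
    """
    args = np.asarray([age, ast, alt, platelets], dtype=float) \
        if np.isscalar(age) else None
    if args is not None:
        if not np.all(args > 0):
            raise DomainError(f"fib4 arguments must be > 0, got {tuple(args)}")
        return (age * ast) / (platelets * math.sqrt(alt))
    age, ast, alt, platelets = (np.asarray(v, dtype=float)
                                for v in (age, ast, alt, platelets))
    if not (np.all(age > 0) and np.all(ast > 0) and np.all(alt > 0)
            and np.all(platelets > 0)):
        raise DomainError("fib4 arguments must be > 0")
    return (age * ast) / (platelets * np.sqrt(alt))


def dfi(age, platelets, ast, alt, bmi):
    """The Diabetes Fibrosis Index evaluated with the published coefficients."""
    for name, v in zip(("age", "platelets", "ast", "alt", "bmi"),
                       (age, platelets, ast, alt, bmi)):
        if not np.all(np.asarray(v) > 0):
            raise DomainError(f"dfi argument {name!r} must be > 0")
    return DFI_MODEL.score(age, platelets, ast, alt, bmi)


@dataclass
class ScoreVector:
    """Per-patient scores for one model on one cohort."""

    model_name: str
    ids: list[str]
    scores: np.ndarray
    cutoff: Optional[float] = None
    at_risk: Optional[np.ndarray] = None


def evaluate_model(m: ScoreModel, c: Cohort, *, cutoff: float | None = None) -> ScoreVector:
    """Score every record in a cohort under model *m*.

    When a cut-off is available (argument overrides model metadata) the
    at-risk flag is score >= cut-off. Missing or non-positive model
    variables raise with the offending record ids.
    """
    bad = [r.id for r in c
           if any(getattr(r, v) is None or not getattr(r, v) > 0
                  for v in MODEL_VARIABLES)]
    if bad:
        raise MissingDataError("model variables missing or non-positive", bad)
    cols = {v: np.array([getattr(r, v) for r in c], dtype=float)
            for v in MODEL_VARIABLES}
    scores = np.asarray(m.score(cols["age"], cols["platelets"], cols["ast"],
                                cols["alt"], cols["bmi"]), dtype=float)
    if len(c) and not np.all(np.isfinite(scores)):
        raise DomainError("non-finite score produced")
    cut = cutoff if cutoff is not None else m.cutoff
    at_risk = (scores >= cut) if cut is not None else None
    return ScoreVector(m.name, c.ids(), scores, cut, at_risk)


def fib4_scores(c: Cohort, *, cutoff: float | None = FIB4_CUTOFF) -> ScoreVector:
    """FIB-4 for every record, classified at *cutoff* (default 1.3)."""
    age = np.array([r.age for r in c], float)
    ast = np.array([r.ast for r in c], float)
    alt = np.array([r.alt for r in c], float)
    plt = np.array([r.platelets for r in c], float)
    scores = fib4(age, ast, alt, plt) if len(c) else np.array([])
    at_risk = (scores >= cutoff) if cutoff is not None else None
    return ScoreVector("fib4", c.ids(), scores, cutoff, at_risk)


# -- model (de)serialization: flat key = value text -------------------------

def save_model(m: ScoreModel, path) -> None:
    lines = [f"name = {m.name}",
             f"theta_age = {float(m.theta_age)!r}",
             f"platelets_amplitude = {float(m.platelets.amplitude)!r}",
             f"platelets_curvature = {float(m.platelets.curvature)!r}",
             f"ast_amplitude = {float(m.ast.amplitude)!r}",
             f"ast_curvature = {float(m.ast.curvature)!r}",
             f"theta_alt = {float(m.theta_alt)!r}",
             f"bmi_amplitude = {float(m.bmi.amplitude)!r}",
             f"bmi_curvature = {float(m.bmi.curvature)!r}"]
    if m.cutoff is not None:
        lines.append(f"cutoff = {float(m.cutoff)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> ScoreModel:
    kv = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    try:
        return ScoreModel(
            name=kv.get("name", "model"),
            theta_age=float(kv["theta_age"]),
            platelets=FactoredTerm(float(kv["platelets_amplitude"]),
                                   float(kv["platelets_curvature"])),
            ast=FactoredTerm(float(kv["ast_amplitude"]), float(kv["ast_curvature"])),
            theta_alt=float(kv["theta_alt"]),
            bmi=FactoredTerm(float(kv["bmi_amplitude"]), float(kv["bmi_curvature"])),
            cutoff=float(kv["cutoff"]) if "cutoff" in kv else None,
        )
    except KeyError as e:
        raise ConfigError(f"model file {path} missing key {e}") from None


def packaged_dfi_path():
    """Path to the packaged default DFI model file."""
    return resources.files("diafib").joinpath("data/dfi_model.txt")
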