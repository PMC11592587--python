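"""Logistic-regression risk-factor screening and two-variable interaction
analysis for advanced hepatic fibrosis.

Odds ratios are reported per unit of the covariate (one year of age, one
IU/L of AST, ...) with Wald 95% confidence intervals and two-sided Wald
p-values, matching the reporting convention of clinical risk-factor
tables. Interaction structure between pairs of index variables is
described two ways: an assumption-free empirical prevalence surface over
a quantile-edged 2-D grid, and a smoothed companion from a quadratic
logistic fit (main effects, squares, and the product term). The product
term is tested with a 1-df likelihood-ratio test.

Maximum-likelihood fitting is delegated to statsmodels (IRLS/Newton);
everything reported on top of it is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, advanced_labels, label_t2dm
from .errors import BinningError, RankError, SeparationError

#: Derived covariates resolvable by name in addition to record fields.
_DERIVED = {
    "ast_alt_ratio": lambda r: r.ast / r.alt,
    "sex_male": lambda r: 1.0 if r.sex == "male" else 0.0,
    "t2dm": lambda r: 1.0 if label_t2dm(r) else 0.0,
}


def covariate_matrix(c: Cohort, covariates: Sequence[str]) -> pd.DataFrame:
    """Extract a numeric covariate frame; booleans become 0/1."""
    data = {}
    for name in covariates:
        if name in _DERIVED:
            vals = [_DERIVED[name](r) for r in c]
        else:
            vals = [getattr(r, name) for r in c]
        data[name] = [float(v) for v in vals]
    return pd.DataFrame(data)


@dataclass
class OddsRatioRow:
    covariate: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    beta: float
    se: float


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    for name in X.columns:
        if X[name].nunique() < 2:
            raise RankError(f"covariate {name!r} is constant")
    full = np.column_stack([np.ones(len(X)), arr])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise RankError("design matrix is rank deficient (collinear covariates)")
    if np.linalg.cond(full.T @ full) > 1e12:
        raise RankError("design matrix is numerically singular")


def _find_separator(X: pd.DataFrame, y: np.ndarray) -> Optional[str]:
    for name in X.columns:
        v = X[name].to_numpy(float)
        if v[y].min() > v[~y].max() or v[y].max() < v[~y].min():
            return name
    return None


def _fit_glm(X: np.ndarray, y: np.ndarray):
    model = sm.GLM(y.astype(float), X, family=sm.families.Binomial())
    return model.fit(tol=1e-8, maxiter=200)


def fit_logistic_xy(X: pd.DataFrame, y, *, joint: bool = True) -> list[OddsRatioRow]:
    """Logistic fit of a binary outcome on a covariate frame.

    ``joint=True`` fits one multivariable model (the default, matching a
    jointly adjusted risk-factor table); ``joint=False`` fits one
    single-covariate model per column (crude ORs).
    """
    y = np.asarray(y, bool)
    _check_design(X)
    sep = _find_separator(X, y)

    def one_fit(frame: pd.DataFrame) -> list[OddsRatioRow]:
        design = np.column_stack([np.ones(len(frame)), frame.to_numpy(float)])
        try:
            res = _fit_glm(design, y)
        except Exception as e:  # statsmodels raises various errors on separation
            raise SeparationError(
                f"logistic fit failed{f' (perfect separation in {sep!r})' if sep else ''}: {e}"
            ) from e
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse[1:] > 1e3):
            raise SeparationError(
                "unstable standard errors"
                + (f": perfect separation in covariate {sep!r}" if sep else ""))
        rows = []
        for j, name in enumerate(frame.columns, start=1):
            b, se = float(res.params[j]), float(res.bse[j])
            z = b / se
            rows.append(OddsRatioRow(
                covariate=name,
                odds_ratio=float(np.exp(b)),
                ci_lower=float(np.exp(b - 1.959963984540054 * se)),
                ci_upper=float(np.exp(b + 1.959963984540054 * se)),
                p_value=float(2.0 * stats.norm.sf(abs(z))),
                beta=b, se=se))
        return rows

    if joint:
        return one_fit(X)
    out = []
    for name in X.columns:
        out.extend(one_fit(X[[name]]))
    return out


def fit_logistic(c: Cohort, covariates: Sequence[str], *,
                 joint: bool = True) -> list[OddsRatioRow]:
    """Risk-factor screen: odds ratios for advanced fibrosis (stage >= F3).

    Covariates name record fields or the derived quantities
    ``ast_alt_ratio``, ``sex_male``, ``t2dm``. No standardization is
    applied: ORs are per unit of each covariate.
    """
    return fit_logistic_xy(covariate_matrix(c, covariates),
                           advanced_labels(c), joint=joint)


def odds_ratio_table(rows: list[OddsRatioRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"Covariate": r.covariate, "Odds Ratio": r.odds_ratio,
         "95% CI Lower": r.ci_lower, "95% CI Upper": r.ci_upper,
         "p": r.p_value}
        for r in rows])


# -- two-variable interaction structure -------------------------------------

@dataclass
class InteractionSurface:
    """Empirical prevalence of advanced fibrosis over a 2-D grid, with an
    optional smoothed companion from a quadratic logistic fit."""

    var1: str
    var2: str
    edges1: np.ndarray
    edges2: np.ndarray
    prevalence: np.ndarray      # nan where a cell is empty
    counts: np.ndarray
    smooth: Optional[np.ndarray] = None

    def write(self, path_prefix, sep=",") -> None:
        pd.DataFrame(self.prevalence).to_csv(
            f"{path_prefix}_prevalence.csv", sep=sep, index=False)
        pd.DataFrame(self.counts).to_csv(
            f"{path_prefix}_counts.csv", sep=sep, index=False)
        if self.smooth is not None:
            pd.DataFrame(self.smooth).to_csv(
                f"{path_prefix}_smooth.csv", sep=sep, index=False)


def _quantile_edges(v: np.ndarray, n_bins: int, name: str) -> np.ndarray:
    edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        raise BinningError(
            f"variable {name!r} has too few distinct values for {n_bins} bins")
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def _quadratic_design(x1: np.ndarray, x2: np.ndarray,
                      with_product: bool) -> np.ndarray:
    cols = [np.ones_like(x1), x1, x2, x1 ** 2, x2 ** 2]
    if with_product:
        cols.append(x1 * x2)
    return np.column_stack(cols)


def interaction_surface(c: Cohort, var1: str, var2: str, n_bins: int = 5,
                        *, smooth: bool = True) -> InteractionSurface:
    """Empirical 2-D prevalence surface over quantile-edged bins.

    Cell (i, j) holds the fraction of patients with advanced fibrosis
    among those falling in bin i of *var1* and bin j of *var2*; empty
    cells report prevalence as nan. When *smooth* is set, a companion
    surface from the quadratic logistic model (main effects, squares,
    product) is evaluated at cell-median covariate values.
    """
    if n_bins < 2:
        raise BinningError("n_bins must be >= 2")
    X = covariate_matrix(c, [var1, var2])
    y = np.asarray(advanced_labels(c), bool)
    v1, v2 = X[var1].to_numpy(), X[var2].to_numpy()
    e1 = _quantile_edges(v1, n_bins, var1)
    e2 = _quantile_edges(v2, n_bins, var2)
    i1 = np.clip(np.searchsorted(e1, v1, side="right") - 1, 0, e1.size - 2)
    i2 = np.clip(np.searchsorted(e2, v2, side="right") - 1, 0, e2.size - 2)
    shape = (e1.size - 1, e2.size - 1)
    counts = np.zeros(shape, int)
    hits = np.zeros(shape, int)
    np.add.at(counts, (i1, i2), 1)
    np.add.at(hits, (i1, i2), y.astype(int))
    with np.errstate(invalid="ignore"):
        prev = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)

    smooth_surface = None
    if smooth and 0 < y.sum() < y.size:
        # standardized fit for numerical stability; predictions unchanged
        z1 = (v1 - v1.mean()) / v1.std()
        z2 = (v2 - v2.mean()) / v2.std()
        res = _fit_glm(_quadratic_design(z1, z2, True), y)
        smooth_surface = np.full(shape, np.nan)
        for a in range(shape[0]):
            for b in range(shape[1]):
                mask = (i1 == a) & (i2 == b)
                if mask.any():
                    g1, g2 = np.median(z1[mask]), np.median(z2[mask])
                    eta = _quadratic_design(np.array([g1]), np.array([g2]),
                                            True) @ res.params
                    smooth_surface[a, b] = 1.0 / (1.0 + np.exp(-eta[0]))
    return InteractionSurface(var1, var2, e1, e2, prev, counts, smooth_surface)


def interaction_test(c: Cohort, var1: str, var2: str) -> float:
    """Likelihood-ratio test for a var1 x var2 product effect.

    Compares the quadratic logistic model with the product term against
    the same model without it; the statistic is chi-square with 1 df.
    Returns the p-value.
    """
    X = covariate_matrix(c, [var1, var2])
    _check_design(X)
    y = np.asarray(advanced_labels(c), bool)
    v1 = X[var1].to_numpy()
    v2 = X[var2].to_numpy()
    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    full = _fit_glm(_quadratic_design(z1, z2, True), y)
    reduced = _fit_glm(_quadratic_design(z1, z2, False), y)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    return float(stats.chi2.sf(lr, df=1))
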