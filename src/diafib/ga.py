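"""Real-coded genetic algorithm fitting score coefficients by AUROC.

The derivation engine of the index: coefficients of the
factored-quadratic family (see :mod:`diafib.scores`) are searched to
maximize the empirical AUROC for detecting advanced fibrosis (stage >= F3)
against biopsy labels. AUROC is invariant under monotone transforms and
piecewise constant in the coefficients, so a derivative-free population
search is the natural fit.

The chromosome is the 8-gene vector
``(theta_age, a_plt, c_plt, a_ast, c_ast, theta_alt, a_bmi, c_bmi)``,
matching the factored form of the published index. Fitness is
orientation-corrected, ``max(AUC, 1 - AUC)``: a score and its negation
carry the same ranking information, and the correction removes that sign
symmetry from the search landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from .cohort import Cohort, advanced_labels
from .errors import ConfigError, DegenerateLabelsError, ValidationError
from .scores import MODEL_VARIABLES, DFI_MODEL, ScoreModel, evaluate_model
from .diagnostics import empirical_auc

_PRINTED = DFI_MODEL.genes()

#: Default search box: amplitudes within +/-10x the published magnitudes,
#: curvatures in [0, 0.1].
DEFAULT_BOUNDS = np.array([
    (-10 * abs(_PRINTED[0]), 10 * abs(_PRINTED[0])),   # theta_age
    (-10 * abs(_PRINTED[1]), 10 * abs(_PRINTED[1])),   # a_plt
    (0.0, 0.1),                                        # c_plt
    (-10 * abs(_PRINTED[3]), 10 * abs(_PRINTED[3])),   # a_ast
    (0.0, 0.1),                                        # c_ast
    (-10 * abs(_PRINTED[5]), 10 * abs(_PRINTED[5])),   # theta_alt
    (-10 * abs(_PRINTED[6]), 10 * abs(_PRINTED[6])),   # a_bmi
    (0.0, 0.1),                                        # c_bmi
])


@dataclass
class GAConfig:
    """Hyperparameters of the real-coded GA.

    Defaults follow standard real-coded GA practice — tournament selection
    of size 3, BLX-alpha blend crossover, per-gene Gaussian mutation
    scaled to the gene's range, a small elite carried over unchanged —
    with three refinements that the scale structure of this search space
    demands:

    * the mutation scale anneals geometrically from ``mutation_scale`` to
      ``mutation_scale * mutation_final`` across the run (AUROC is a
      ranking statistic; late progress needs small relative coefficient
      adjustments a fixed large mutation would destroy);
    * the initial population samples gene *magnitudes* log-uniformly over
      three decades below each bound: coefficients and curvatures span
      orders of magnitude, and a curvature's meaningful quantity is the
      peak location 1/(2c), which uniform sampling of c covers only at
      its extreme low end;
    * ``restarts`` independent populations are run and the best result
      kept — the AUROC landscape has strong local optima, and a
      multi-start is the standard insurance.
    """

    population: int = 200
    generations: int = 250
    tournament: int = 3
    crossover_rate: float = 0.9
    blx_alpha: float = 0.5        # blend-crossover expansion beyond the parents
    mutation_scale: float = 0.1   # initial s.d. as a fraction of each gene's range
    mutation_final: float = 0.01  # final scale as a fraction of the initial
    mutation_prob: float = 0.3    # per-gene mutation probability
    elitism: int = 2
    restarts: int = 4
    init: str = "log-uniform"     # or "uniform"
    bounds: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS.copy())
    seed: int = 0

    def validate(self) -> None:
        if self.population < 2:
            raise ConfigError("population must be >= 2")
        if not 0 <= self.elitism < self.population:
            raise ConfigError("elitism must be in [0, population)")
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (8, 2):
            raise ConfigError(f"bounds must be (8, 2), got {b.shape}")
        if not np.all(np.isfinite(b)):
            raise ConfigError("gene bounds must be finite")
        if not np.all(b[:, 0] < b[:, 1]):
            raise ConfigError("each bound must satisfy low < high")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ConfigError("crossover_rate must be in [0, 1]")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if self.init not in ("log-uniform", "uniform"):
            raise ConfigError(f"unknown init {self.init!r}")


@dataclass
class FitResult:
    """Outcome of one GA run."""

    best_model: ScoreModel
    best_fitness: float
    flipped: bool                 # raw AUC of best model was < 0.5
    trajectory_best: list[float]  # per-generation best fitness
    trajectory_mean: list[float]  # per-generation population mean fitness
    seed: int

    def write_trace(self, path, sep=",") -> None:
        import pandas as pd
        pd.DataFrame({"generation": range(len(self.trajectory_best)),
                      "best": self.trajectory_best,
                      "mean": self.trajectory_mean}).to_csv(path, sep=sep,
                                                            index=False)


def fitness(m: ScoreModel, c: Cohort) -> float:
    """Orientation-corrected AUROC of model *m* for advanced fibrosis."""
    auc = empirical_auc(evaluate_model(m, c).scores, advanced_labels(c))
    return max(auc, 1.0 - auc)


def _design(c: Cohort) -> np.ndarray:
    """n x 8 design: age, plt, plt^2, ast, ast^2, alt, bmi, bmi^2."""
    cols = {v: np.array([getattr(r, v) for r in c], float)
            for v in MODEL_VARIABLES}
    return np.column_stack([
        cols["age"],
        cols["platelets"], cols["platelets"] ** 2,
        cols["ast"], cols["ast"] ** 2,
        cols["alt"],
        cols["bmi"], cols["bmi"] ** 2,
    ])


def _expand_weights(genes: np.ndarray) -> np.ndarray:
    """Map gene matrix (k x 8) to linear weights over the design columns:
    a*X*(1 - c*X) expands to a*X - a*c*X^2."""
    g = np.atleast_2d(genes)
    return np.column_stack([
        g[:, 0],
        g[:, 1], -g[:, 1] * g[:, 2],
        g[:, 3], -g[:, 3] * g[:, 4],
        g[:, 5],
        g[:, 6], -g[:, 6] * g[:, 7],
    ])


def _population_auc(X: np.ndarray, genes: np.ndarray, y: np.ndarray):
    """Raw tie-corrected AUC for every candidate in one vectorized pass."""
    scores = X @ _expand_weights(genes).T            # n x k
    ranks = stats.rankdata(scores, axis=0)
    m = int(y.sum())
    n = y.size - m
    return (ranks[y].sum(axis=0) - m * (m + 1) / 2.0) / (m * n)


def _tournament(rng, fit: np.ndarray, k: int, count: int) -> np.ndarray:
    """Indices of *count* tournament winners; ties go to the earlier
    population index for determinism."""
    cand = np.sort(rng.integers(0, fit.size, size=(count, k)), axis=1)
    return cand[np.arange(count), np.argmax(fit[cand], axis=1)]


_SIGN_GENES = np.array([0, 1, 3, 5, 6])  # linear/amplitude genes


def _initial_population(rng, cfg: GAConfig) -> np.ndarray:
    low, high = cfg.bounds[:, 0], cfg.bounds[:, 1]
    if cfg.init == "uniform":
        return low + rng.random((cfg.population, 8)) * (high - low)
    # log-uniform magnitudes over three decades below each bound; genes
    # whose bounds straddle zero get a random sign
    pop = np.empty((cfg.population, 8))
    for j in range(8):
        bound = max(abs(low[j]), abs(high[j]))
        mag = bound * 10.0 ** rng.uniform(-3.0, 0.0, cfg.population)
        if low[j] < 0 < high[j]:
            mag *= rng.choice([-1.0, 1.0], cfg.population)
        elif high[j] <= 0:
            mag = -mag
        pop[:, j] = np.clip(mag, low[j], high[j])
    return pop


def _run_once(X, y, cfg: GAConfig, rng):
    low, high = cfg.bounds[:, 0], cfg.bounds[:, 1]
    span = high - low
    can_flip = np.all(low[_SIGN_GENES] <= -high[_SIGN_GENES])

    def canonicalize(pop, raw):
        """Flip reversed-orientation members (raw AUC < 0.5) to positive
        orientation so blend crossover mates coherent parents; a mix of
        mirror-image parents would otherwise breed toward the useless
        zero score. Only possible when the amplitude bounds admit the
        negation."""
        if not can_flip:
            return pop, raw
        rev = raw < 0.5
        pop[np.ix_(rev, _SIGN_GENES)] *= -1.0
        raw[rev] = 1.0 - raw[rev]
        return pop, raw

    pop = _initial_population(rng, cfg)
    pop, raw = canonicalize(pop, _population_auc(X, pop, y))
    fit = np.maximum(raw, 1.0 - raw)

    i0 = int(np.argmax(fit))
    best_genes, best_fit, best_raw = pop[i0].copy(), float(fit[i0]), float(raw[i0])
    traj_best, traj_mean = [best_fit], [float(fit.mean())]

    decay = cfg.mutation_final ** (1.0 / max(cfg.generations - 1, 1)) \
        if cfg.generations > 1 else 1.0
    for gen in range(cfg.generations):
        scale = cfg.mutation_scale * decay ** gen
        order = np.argsort(-fit, kind="stable")
        elite = pop[order[:cfg.elitism]].copy()
        n_children = cfg.population - cfg.elitism
        p1 = pop[_tournament(rng, fit, cfg.tournament, n_children)]
        p2 = pop[_tournament(rng, fit, cfg.tournament, n_children)]
        u = rng.uniform(-cfg.blx_alpha, 1.0 + cfg.blx_alpha, (n_children, 8))
        cross = rng.random(n_children) < cfg.crossover_rate
        children = np.where(cross[:, None], u * p1 + (1 - u) * p2, p1)
        mutate = rng.random((n_children, 8)) < cfg.mutation_prob
        noise = rng.normal(0.0, scale, (n_children, 8)) * span
        children = np.clip(children + mutate * noise, low, high)
        pop = np.vstack([elite, children])

        pop, raw = canonicalize(pop, _population_auc(X, pop, y))
        fit = np.maximum(raw, 1.0 - raw)
        i = int(np.argmax(fit))
        if fit[i] > best_fit:
            best_genes, best_fit, best_raw = pop[i].copy(), float(fit[i]), float(raw[i])
        traj_best.append(best_fit)
        traj_mean.append(float(fit.mean()))
    return best_genes, best_fit, best_raw, traj_best, traj_mean


def fit_ga(c: Cohort, template: ScoreModel | None = None,
           cfg: GAConfig | None = None) -> FitResult:
    """Fit score coefficients maximizing AUROC on cohort *c*.

    *template* names the model family (its variables must be present in
    every record); the search itself starts from random populations
    within ``cfg.bounds``. ``cfg.restarts`` independent populations are
    evolved and the best kept. Fully reproducible under ``cfg.seed``; the
    returned model's fitness is at least that of every initial-population
    member. The fitted model carries no cut-off — choose one afterwards
    with :func:`diafib.diagnostics.select_cutoff`.
    """
    cfg = cfg or GAConfig()
    cfg.validate()
    y = np.asarray(advanced_labels(c), bool)
    if y.all() or not y.any():
        raise DegenerateLabelsError("GA fitting needs both outcome classes")
    if template is not None:
        evaluate_model(template, c)  # raises on missing variables
    X = _design(c)

    best = None
    for child_seq in np.random.SeedSequence(cfg.seed).spawn(cfg.restarts):
        result = _run_once(X, y, cfg, np.random.default_rng(child_seq))
        if best is None or result[1] > best[1]:
            best = result
    best_genes, best_fit, best_raw, traj_best, traj_mean = best

    low, high = cfg.bounds[:, 0], cfg.bounds[:, 1]
    flipped = best_raw < 0.5
    genes = best_genes
    if flipped:
        # negating the amplitude/linear genes reverses the score's sign
        # (curvatures stay non-negative); only applied when the negation
        # stays inside the search box, else the flag alone records the
        # reversed orientation
        neg = best_genes.copy()
        neg[_SIGN_GENES] *= -1.0
        if np.all((neg >= low) & (neg <= high)):
            genes = neg
    model = ScoreModel.from_genes(genes, name="ga-fit")
    return FitResult(model, best_fit, flipped, traj_best, traj_mean, cfg.seed)
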