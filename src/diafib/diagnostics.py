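"""ROC analysis, correlated-AUC comparison, cut-off selection, and
age-stratified diagnostic reporting.

The AUC estimator throughout is the tie-corrected Mann–Whitney statistic:
the probability that a randomly chosen diseased patient outscores a
randomly chosen non-diseased one, counting ties as one half. Correlated
AUCs computed on the same patients (e.g. DFI vs FIB-4) are compared with
DeLong's structural-components test, with a paired-bootstrap alternative.

Classification convention everywhere: a patient is called at-risk when
score >= cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, advanced_labels
from .errors import (AlignmentError, DegenerateLabelsError, DegenerateSplitError,
                     PolicyInfeasibleError, ValidationError)
from .scores import ScoreModel, ScoreVector, evaluate_model, fib4_scores

#: Age bands of the published per-age performance table, plus a catch-all
#: for ages above 75 (the published table prints none). Each band is
#: (label, low, high] on age.
PUBLISHED_AGE_BANDS = (
    ("~25", -np.inf, 25.0),
    ("26~35", 25.0, 35.0),
    ("36~45", 35.0, 45.0),
    ("46~55", 45.0, 55.0),
    ("56~65", 55.0, 65.0),
    ("66~75", 65.0, 75.0),
    ("76+", 75.0, np.inf),
)


def _check_classes(labels: np.ndarray) -> None:
    if labels.size == 0 or labels.all() or not labels.any():
        raise DegenerateLabelsError("need at least one record of each class")


def _as_arrays(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise AlignmentError(f"scores {s.shape} and labels {y.shape} misaligned")
    return s, y


def empirical_auc(scores, labels) -> float:
    """Tie-corrected Mann–Whitney AUC.

    Equals (#{(pos, neg) pairs with pos > neg} + 0.5 * #ties) / (n_pos * n_neg),
    and the trapezoidal area under the empirical ROC curve.
    """
    s, y = _as_arrays(scores, labels)
    _check_classes(y)
    m = int(y.sum())
    n = y.size - m
    ranks = stats.rankdata(s)
    return (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)


@dataclass
class RocCurve:
    """Empirical ROC: one operating point per distinct score, plus
    sentinels at -inf (everyone positive) and +inf (everyone negative)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def roc_curve(scores, labels) -> RocCurve:
    """Build the empirical ROC for classification at score >= threshold."""
    s, y = _as_arrays(scores, labels)
    _check_classes(y)
    m = int(y.sum())
    n = y.size - m
    uniq, inv = np.unique(s, return_inverse=True)
    pos_at = np.bincount(inv[y], minlength=uniq.size)
    neg_at = np.bincount(inv[~y], minlength=uniq.size)
    pos_ge = m - np.concatenate(([0], np.cumsum(pos_at)[:-1]))
    neg_lt = np.concatenate(([0], np.cumsum(neg_at)[:-1]))
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    sens = np.concatenate(([1.0], pos_ge / m, [0.0]))
    spec = np.concatenate(([0.0], neg_lt / n, [1.0]))
    return RocCurve(thresholds, sens, spec, empirical_auc(s, y), m, n)


# -- correlated AUC comparison ----------------------------------------------

@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float
    method: str = "delong"


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)
    for each score row, via midranks."""
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    v10 = np.empty((scores.shape[0], m))
    v01 = np.empty((scores.shape[0], n))
    for k in range(scores.shape[0]):
        tx = stats.rankdata(pos[k])
        ty = stats.rankdata(neg[k])
        tz = stats.rankdata(np.concatenate([pos[k], neg[k]]))
        v10[k] = (tz[:m] - tx) / n
        v01[k] = 1.0 - (tz[m:] - ty) / m
    return v10, v01


def delong_covariance(scores_a, scores_b, labels):
    """AUCs and the 2x2 covariance matrix of their estimators."""
    sa, y = _as_arrays(scores_a, labels)
    sb, _ = _as_arrays(scores_b, labels)
    if sa.shape != sb.shape:
        raise AlignmentError("score vectors have different lengths")
    _check_classes(y)
    S = np.vstack([sa, sb])
    v10, v01 = _structural_components(S, y)
    aucs = v10.mean(axis=1)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    return aucs, cov


def compare_auc(scores_a, scores_b, labels, *, method: str = "delong",
                n_boot: int = 2000, seed: int | None = None) -> AucComparison:
    """Paired comparison of two correlated AUCs on the same patients.

    ``method="delong"`` (default) uses the structural-components variance
    with a two-sided normal p-value; ``method="bootstrap"`` resamples
    patients with replacement, keeping the pairing, and reports the
    percentile-z p-value from the bootstrap variance.
    """
    aucs, cov = delong_covariance(scores_a, scores_b, labels)
    diff = float(aucs[0] - aucs[1])
    if method == "delong":
        var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    elif method == "bootstrap":
        var = float(paired_bootstrap_variance(scores_a, scores_b, labels,
                                              n_boot=n_boot, seed=seed))
    else:
        raise ValidationError(f"unknown method {method!r}")
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if diff == 0 else float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(float(aucs[0]), float(aucs[1]), diff, var, float(z),
                         p, method)


def paired_bootstrap_variance(scores_a, scores_b, labels, *, n_boot=2000,
                              seed=None) -> float:
    """Variance of the AUC difference under paired patient resampling.

    Vectorized over replicates with all-pairs comparison; intended for
    small cohorts where the O(B * n^2) cost is trivial. Replicates that
    lose one class entirely are redrawn implicitly by rejection.
    """
    sa, y = _as_arrays(scores_a, labels)
    sb, _ = _as_arrays(scores_b, labels)
    _check_classes(y)
    rng = np.random.default_rng(seed)
    n = y.size
    diffs = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        yb = y[idx]
        ok = yb.any(axis=1) & ~yb.all(axis=1)
        if not ok.any():
            continue
        idx, yb = idx[ok], yb[ok]
        for s, out in ((sa, 0), (sb, 1)):
            sb_ = s[idx]
            gt = (sb_[:, :, None] > sb_[:, None, :]).astype(float)
            gt += 0.5 * (sb_[:, :, None] == sb_[:, None, :])
            pairmask = yb[:, :, None] & ~yb[:, None, :]
            npairs = pairmask.sum(axis=(1, 2))
            auc = (gt * pairmask).sum(axis=(1, 2)) / npairs
            if out == 0:
                auc_a = auc
            else:
                auc_b = auc
        take = auc_a - auc_b
        diffs[filled:filled + take.size] = take
        filled += take.size
    return float(np.var(diffs, ddof=1))


# -- cut-off selection ------------------------------------------------------

def _finite_points(roc: RocCurve):
    fin = np.isfinite(roc.thresholds)
    return roc.thresholds[fin], roc.sensitivity[fin], roc.specificity[fin]


def _gap_cutoff(thresholds: np.ndarray, i: int) -> float:
    """Cut-off placed in the gap below distinct score thresholds[i]; the
    returned value classifies identically to thresholds[i] itself."""
    if i == 0:
        return float(thresholds[0])
    return float(0.5 * (thresholds[i - 1] + thresholds[i]))


def npv_from_operating_point(sens, spec, prevalence):
    """Negative predictive value at an operating point for a given
    prevalence; nan when no patient tests negative."""
    sens = np.asarray(sens, float)
    spec = np.asarray(spec, float)
    denom = spec * (1 - prevalence) + (1 - sens) * prevalence
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, spec * (1 - prevalence) / denom, np.nan)


def select_cutoff(roc: RocCurve, policy: str, *, target: float | None = None,
                  prevalence: float | None = None) -> float:
    """Select a cut-off from an ROC curve under a named policy.

    Policies
    --------
    ``min_sensitivity``
        Largest cut-off whose sensitivity is >= *target*.
    ``youden``
        Maximize sensitivity + specificity - 1, ties broken toward higher
        sensitivity; on separable data this lands mid-gap between the
        classes.
    ``min_npv``
        Largest cut-off whose NPV (computed from sensitivity, specificity
        and *prevalence*) is >= *target*.

    Returned cut-offs are placed at the midpoint of the score gap below
    the qualifying operating point, so classification at the returned
    value reproduces that operating point exactly. Infeasible targets
    raise :class:`~diafib.errors.PolicyInfeasibleError` carrying the
    attainable frontier.
    """
    thr, sens, spec = _finite_points(roc)
    if thr.size == 0:
        raise ValidationError("degenerate ROC: no finite thresholds")
    frontier = pd.DataFrame({"cutoff": thr, "sensitivity": sens,
                             "specificity": spec})
    if policy == "min_sensitivity":
        if target is None:
            raise ValidationError("min_sensitivity requires target")
        ok = np.nonzero(sens >= target)[0]
        if ok.size == 0:
            raise PolicyInfeasibleError(
                f"no cut-off attains sensitivity >= {target}", frontier)
        return _gap_cutoff(thr, int(ok[-1]))
    if policy == "youden":
        j = sens + spec - 1.0
        best = j.max()
        # ties toward higher sensitivity = lowest qualifying threshold
        i = int(np.nonzero(np.isclose(j, best))[0][0])
        return _gap_cutoff(thr, i)
    if policy == "min_npv":
        if target is None or prevalence is None:
            raise ValidationError("min_npv requires target and prevalence")
        npv = npv_from_operating_point(sens, spec, prevalence)
        ok = np.nonzero(npv >= target)[0]
        if ok.size == 0:
            frontier = frontier.assign(npv=npv)
            raise PolicyInfeasibleError(
                f"no cut-off attains NPV >= {target}", frontier)
        return _gap_cutoff(thr, int(ok[-1]))
    raise ValidationError(f"unknown policy {policy!r}")


# -- stratified diagnostic report -------------------------------------------

@dataclass
class BandMetrics:
    """Confusion-matrix metrics for one age band at a fixed cut-off."""

    band: str
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    auroc: Optional[float]
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


@dataclass
class DiagnosticReport:
    """Per-age-band and overall performance at one global cut-off."""

    model_name: str
    cutoff: float
    bands: list[BandMetrics] = field(default_factory=list)
    overall: Optional[BandMetrics] = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [self.overall] + self.bands if self.overall else self.bands
        return pd.DataFrame([
            {"Age Group": b.band, "n": b.n, "AUROC": b.auroc, "Acc": b.accuracy,
             "Sens": b.sensitivity, "Spec": b.specificity, "PPV": b.ppv,
             "NPV": b.npv}
            for b in rows])

    def write(self, path, sep=",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def _ratio(num, den):
    return num / den if den > 0 else None


def _band_metrics(label, scores, labels, cutoff) -> BandMetrics:
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    n = labels.size
    try:
        auroc = empirical_auc(scores, labels)
    except DegenerateLabelsError:
        auroc = None
    return BandMetrics(
        band=label, n=n, tp=tp, fp=fp, tn=tn, fn=fn, auroc=auroc,
        accuracy=_ratio(tp + tn, n),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def stratified_report(c: Cohort, m: ScoreModel | str, cutoff: float,
                      bands: Sequence[tuple] = PUBLISHED_AGE_BANDS) -> DiagnosticReport:
    """Confusion-matrix metrics per age band at one fixed global cut-off.

    Band AUROC is computed from band-local scores and labels; bands with a
    single outcome class report AUROC as absent. *m* may be a
    :class:`~diafib.scores.ScoreModel` or the string ``"fib4"``.
    Bands are (label, low, high] intervals and must not overlap.
    """
    lows = sorted((b[1], b[2]) for b in bands)
    for (l1, h1), (l2, h2) in zip(lows, lows[1:]):
        if l2 < h1:
            raise ValidationError("age bands overlap")
    sv: ScoreVector = fib4_scores(c, cutoff=None) if m == "fib4" \
        else evaluate_model(m, c)
    scores = sv.scores
    labels = np.asarray(advanced_labels(c), bool)
    ages = np.array([r.age for r in c], float)
    name = "fib4" if m == "fib4" else m.name

    report = DiagnosticReport(model_name=name, cutoff=cutoff)
    report.overall = _band_metrics("Total", scores, labels, cutoff)
    for label, low, high in bands:
        mask = (ages > low) & (ages <= high)
        report.bands.append(_band_metrics(label, scores[mask], labels[mask],
                                          cutoff))
    return report


def split_cohort(c: Cohort, fraction: float, seed: int,
                 stratify_on: str = "advanced") -> tuple[Cohort, Cohort]:
    """Label-stratified random partition into (derivation, validation).

    *fraction* is the derivation share, in the open interval (0, 1). Both
    parts retain both classes whenever each class has at least two
    members. Reproducible under *seed*; record order within each part
    follows the original cohort order.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    if len(c) < 2:
        raise DegenerateSplitError("need at least 2 records to split")
    if stratify_on == "advanced":
        strata = np.asarray(advanced_labels(c), bool)
    else:
        strata = np.array([getattr(r, stratify_on) for r in c])
    rng = np.random.default_rng(seed)
    in_first = np.zeros(len(c), dtype=bool)
    for value in np.unique(strata):
        idx = np.nonzero(strata == value)[0]
        rng.shuffle(idx)
        k = int(round(fraction * idx.size))
        if idx.size >= 2:
            k = min(max(k, 1), idx.size - 1)
        in_first[idx[:k]] = True
    first = [r for r, f in zip(c.records, in_first) if f]
    second = [r for r, f in zip(c.records, in_first) if not f]
    return (c.subset(first, f"{c.provenance}[derivation]"),
            c.subset(second, f"{c.provenance}[validation]"))
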