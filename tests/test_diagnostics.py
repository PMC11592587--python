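"""ROC/AUC estimation, DeLong comparison, cut-off policies, stratified
reports, and cohort splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diafib.cohort import Cohort
from diafib.diagnostics import (PUBLISHED_AGE_BANDS, compare_auc, empirical_auc,
                                npv_from_operating_point,
                                paired_bootstrap_variance, roc_curve,
                                select_cutoff, split_cohort,
                                stratified_report)
from diafib.errors import (DegenerateLabelsError, DegenerateSplitError,
                           PolicyInfeasibleError, ValidationError)
from diafib.scores import FactoredTerm, ScoreModel

from conftest import brute_force_auc, labeled_cohort, make_record

AST_ONLY = ScoreModel("ast-only", 0.0, FactoredTerm(0, 0), FactoredTerm(1, 0),
                      0.0, FactoredTerm(0, 0))


class TestEmpiricalAuc:
    def test_four_point_instance(self):
        """pos {3,1} vs neg {2,0}: 3 of 4 pairs concordant."""
        assert empirical_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation(self):
        assert empirical_auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert empirical_auc([2, 2, 2, 2], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_auc([1, 2], [1, 1])

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_pair_counting(self, data):
        """Rank-based estimator equals brute-force pair counting on
        random instances of size <= 30 (ties included)."""
        n = data.draw(st.integers(2, 30))
        scores = data.draw(st.lists(
            st.integers(-5, 5).map(float), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n)
                           .filter(lambda l: any(l) and not all(l)))
        assert empirical_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        if not (y.any() and not y.all()):
            y[:2] = [True, False]
        a0 = empirical_auc(s, y)
        assert empirical_auc(np.exp(s), y) == pytest.approx(a0)
        assert empirical_auc(3 * s + 7, y) == pytest.approx(a0)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        s = rng.normal(size=200).round(1)   # force ties
        y = rng.random(200) < 0.3
        assert empirical_auc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestRocCurve:
    def test_four_point_enumeration(self):
        roc = roc_curve([3, 1, 2, 0], [1, 1, 0, 0])
        assert roc.auc == 0.75
        # sentinels
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
        assert roc.sensitivity[-1] == 0.0 and roc.specificity[-1] == 1.0
        # hand-enumerated operating points at thresholds 0,1,2,3
        np.testing.assert_allclose(roc.sensitivity[1:-1], [1, 1, 0.5, 0.5])
        np.testing.assert_allclose(roc.specificity[1:-1], [0, 0.5, 0.5, 1.0])

    def test_auc_equals_trapezoid_of_stored_points(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=150).round(1)
        y = rng.random(150) < 0.35
        roc = roc_curve(s, y)
        fpr = 1.0 - roc.specificity
        area = -np.trapezoid(roc.sensitivity, fpr)  # fpr decreasing
        assert area == pytest.approx(roc.auc)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        roc = roc_curve(rng.normal(size=80), rng.random(80) < 0.5)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)


class TestCompareAuc:
    def test_identical_scores(self):
        s = [1.0, 2.0, 3.0, 4.0]
        y = [0, 0, 1, 1]
        cmp_ = compare_auc(s, s, y)
        assert cmp_.difference == 0.0 and cmp_.p_value == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        y = rng.random(40) < 0.5
        a, b = rng.normal(size=40), rng.normal(size=40)
        ab = compare_auc(a, b, y)
        ba = compare_auc(b, a, y)
        assert ab.difference == pytest.approx(-ba.difference)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_variance_matches_paired_bootstrap(self):
        """DeLong variance of the AUC difference agrees with a
        100k-replicate paired bootstrap on a fixed 12-patient instance."""
        rng = np.random.default_rng(2024)
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
        a = np.array([3.1, 2.2, 2.9, 1.4, 2.0, 1.1, 0.4, 1.9, 0.7, 1.3, 0.2, 1.6])
        b = a + rng.normal(0, 0.8, 12)
        cmp_ = compare_auc(a, b, y)
        boot = paired_bootstrap_variance(a, b, y, n_boot=100_000, seed=5)
        assert cmp_.variance == pytest.approx(boot, rel=0.15)

    def test_type_i_error_under_permutation_null(self):
        """Permuting labels breaks any score-label association; the DeLong
        test should then reject at ~alpha."""
        rng = np.random.default_rng(31)
        n, reps = 80, 2000
        base = rng.normal(size=n)
        a = base + rng.normal(0, 1.0, n)
        b = base + rng.normal(0, 1.0, n)
        y0 = np.zeros(n, bool)
        y0[:30] = True
        hits = 0
        for _ in range(reps):
            y = rng.permutation(y0)
            if compare_auc(a, b, y).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_bootstrap_method_runs(self):
        rng = np.random.default_rng(8)
        y = rng.random(30) < 0.4
        a, b = rng.normal(size=30), rng.normal(size=30)
        cmp_ = compare_auc(a, b, y, method="bootstrap", n_boot=500, seed=1)
        assert cmp_.method == "bootstrap" and cmp_.variance > 0


class TestSelectCutoff:
    def test_min_sensitivity_full_recall(self):
        """Target sensitivity 1.0 lands just below the lowest positive."""
        roc = roc_curve([3, 1, 2, 0], [1, 1, 0, 0])
        cut = select_cutoff(roc, "min_sensitivity", target=1.0)
        assert cut == pytest.approx(0.5)  # midpoint of gap (0, 1)
        # classification at the returned cut-off attains the target
        sens = np.mean([s >= cut for s in (3, 1)])
        assert sens >= 1.0

    def test_min_sensitivity_guarantee(self):
        rng = np.random.default_rng(17)
        s = rng.normal(size=100).round(1)
        y = rng.random(100) < 0.3
        roc = roc_curve(s, y)
        for target in (0.7, 0.9, 0.95):
            cut = select_cutoff(roc, "min_sensitivity", target=target)
            assert np.mean(s[y] >= cut) >= target

    def test_youden_separable_gap_midpoint(self):
        roc = roc_curve([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert select_cutoff(roc, "youden") == pytest.approx(6.5)

    def test_infeasible_target_carries_frontier(self):
        roc = roc_curve([3, 1, 2, 0], [1, 1, 0, 0])
        with pytest.raises(PolicyInfeasibleError) as exc:
            select_cutoff(roc, "min_sensitivity", target=1.1)
        assert exc.value.frontier is not None
        assert "sensitivity" in exc.value.frontier.columns

    def test_min_npv_policy(self):
        rng = np.random.default_rng(23)
        s = np.concatenate([rng.normal(1.2, 1, 40), rng.normal(0, 1, 160)])
        y = np.repeat([True, False], [40, 160])
        roc = roc_curve(s, y)
        cut = select_cutoff(roc, "min_npv", target=0.9, prevalence=0.2)
        sens = np.mean(s[y] >= cut)
        spec = np.mean(s[~y] < cut)
        assert npv_from_operating_point(sens, spec, 0.2) >= 0.9


class TestStratifiedReport:
    def test_hand_built_confusion_matrices(self):
        """Eight patients, two bands, AST-only score at cut-off 50."""
        recs = [
            make_record("a1", age=30, ast=60, fibrosis_stage=3),   # TP
            make_record("a2", age=32, ast=40, fibrosis_stage=3),   # FN
            make_record("a3", age=35, ast=55, fibrosis_stage=1),   # FP
            make_record("a4", age=28, ast=30, fibrosis_stage=0),   # TN
            make_record("b1", age=60, ast=70, fibrosis_stage=4),   # TP
            make_record("b2", age=62, ast=45, fibrosis_stage=1),   # TN
            make_record("b3", age=65, ast=52, fibrosis_stage=1),   # FP
            make_record("b4", age=58, ast=80, fibrosis_stage=2),   # FP
        ]
        bands = (("young", 0.0, 45.0), ("old", 45.0, 120.0))
        rep = stratified_report(Cohort(recs), AST_ONLY, 50.0, bands)
        young, old = rep.bands
        assert (young.tp, young.fp, young.tn, young.fn) == (1, 1, 1, 1)
        assert young.accuracy == 0.5 and young.sensitivity == 0.5
        assert (old.tp, old.fp, old.tn, old.fn) == (1, 2, 1, 0)
        assert old.sensitivity == 1.0 and old.specificity == pytest.approx(1 / 3)
        assert rep.overall.n == 8
        assert sum(b.n for b in rep.bands) == 8

    def test_single_band_equals_overall(self, synthetic_cohort):
        from diafib.scores import DFI_MODEL
        rep = stratified_report(synthetic_cohort, DFI_MODEL, 715.0,
                                (("all", 0.0, 200.0),))
        only = rep.bands[0]
        for attr in ("auroc", "accuracy", "sensitivity", "specificity",
                     "ppv", "npv", "n"):
            assert getattr(only, attr) == getattr(rep.overall, attr)

    def test_empty_band_flagged_sizes_still_sum(self, synthetic_cohort):
        rep = stratified_report(synthetic_cohort,
                                "fib4", 1.3,
                                (("impossible", 150.0, 200.0),
                                 ("everyone", 0.0, 150.0)))
        empty, full = rep.bands
        assert empty.n == 0 and empty.auroc is None and empty.accuracy is None
        assert empty.n + full.n == len(synthetic_cohort)

    def test_accuracy_reproducible_from_confusion_matrix(self, synthetic_cohort):
        from diafib.scores import DFI_MODEL
        rep = stratified_report(synthetic_cohort, DFI_MODEL, 715.0,
                                PUBLISHED_AGE_BANDS)
        for b in [rep.overall] + rep.bands:
            if b.n:
                assert b.accuracy == pytest.approx((b.tp + b.tn) / b.n)
                assert b.tp + b.fp + b.tn + b.fn == b.n

    def test_overlapping_bands_rejected(self, synthetic_cohort):
        from diafib.scores import DFI_MODEL
        with pytest.raises(ValidationError):
            stratified_report(synthetic_cohort, DFI_MODEL, 715.0,
                              (("a", 0.0, 50.0), ("b", 40.0, 90.0)))


class TestSplitCohort:
    def test_stratification_arithmetic(self):
        cohort = labeled_cohort(range(100, 130), range(200, 270))
        assert len(cohort) == 100
        train, test = split_cohort(cohort, 0.7, seed=3)
        assert len(train) == 70 and len(test) == 30
        n_pos_train = sum(r.fibrosis_stage >= 3 for r in train)
        assert abs(n_pos_train - 21) <= 1

    def test_deterministic(self):
        cohort = labeled_cohort(range(10), range(10, 40))
        a1, b1 = split_cohort(cohort, 0.6, seed=9)
        a2, b2 = split_cohort(cohort, 0.6, seed=9)
        assert a1.ids() == a2.ids() and b1.ids() == b2.ids()
        a3, _ = split_cohort(cohort, 0.6, seed=10)
        assert a1.ids() != a3.ids()

    def test_both_parts_keep_both_classes(self):
        cohort = labeled_cohort([5.0, 6.0], range(20))
        train, test = split_cohort(cohort, 0.5, seed=0)
        for part in (train, test):
            stages = {r.fibrosis_stage >= 3 for r in part}
            assert stages == {True, False}

    def test_invalid_fraction(self):
        cohort = labeled_cohort([1.0], [2.0])
        with pytest.raises(ValidationError):
            split_cohort(cohort, 0.0, seed=1)

    def test_too_small(self):
        with pytest.raises(DegenerateSplitError):
            split_cohort(Cohort([make_record()]), 0.5, seed=1)
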