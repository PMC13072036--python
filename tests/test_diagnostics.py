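import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from evquant import (
    CohortSpec,
    chi_square,
    confusion_at,
    derive_index,
    ev_index,
    evaluate_cohort,
    fit_logistic_irls,
    logistic_cv,
    normalize_score,
    roc_curve,
    simulate_cohort,
    stratified_kfold,
    two_proportion_ztest,
    welch_ttest,
    youden_cutoff,
)


class TestNormalizeScore:
    def test_arithmetic(self):
        assert normalize_score(100, (20, 20)) == 80.0

    def test_floor_at_zero(self):
        assert normalize_score(10, (20, 20)) == 0.0

    def test_missing_controls_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_score(100, ())

    @given(
        sample=st.integers(0, 10_000),
        controls=st.lists(st.integers(0, 1000), min_size=1, max_size=4),
        c=st.integers(0, 500),
    )
    def test_invariant_under_common_additive_offset(self, sample, controls, c):
        base = normalize_score(sample, controls)
        shifted = normalize_score(sample + c, [x + c for x in controls])
        assert shifted == pytest.approx(base)


class TestEVIndex:
    def test_zero_score_zero_index(self):
        assert ev_index(0.0, 3e9) == 0.0

    def test_doubling_concentration_halves_index(self):
        assert ev_index(20, 2e9) == pytest.approx(ev_index(20, 1e9) / 2)

    def test_arithmetic(self):
        assert ev_index(20, 2e9, scale=1e9) == 10.0

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ev_index(5.0, 0.0)


class TestROC:
    def test_perfect_separation_auc_one(self):
        auc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc
        assert auc == 1.0

    def test_total_ties_auc_half(self):
        assert roc_curve([5.0] * 8, [0, 1] * 4).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_curve_monotone_with_unit_endpoints(self, rng):
        x = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        roc = roc_curve(x, y)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert (roc.sensitivity[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.sensitivity[-1], roc.fpr[-1]) == (1.0, 1.0)

    def test_auc_equals_mann_whitney(self, rng):
        """Trapezoidal AUC is the Mann-Whitney U statistic over n1*n2."""
        for _ in range(25):
            n1, n0 = rng.integers(5, 40, size=2)
            x = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
            if rng.random() < 0.5:
                x = np.round(x)  # force ties
            y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            auc = roc_curve(x, y).auc
            u = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        x = rng.normal(size=200)
        y = (x + rng.normal(size=200) > 0).astype(int)
        assert roc_curve(x, y).auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)


class TestYouden:
    def test_separated_groups(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        cutoff, j = youden_cutoff(roc)
        assert j == 1.0
        assert 3 < cutoff < 10

    def test_all_ties_j_zero(self):
        cutoff, j = youden_cutoff(roc_curve([5.0] * 8, [0, 1] * 4))
        assert j == 0.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(25):
            x = rng.normal(size=50)
            y = rng.integers(0, 2, size=50)
            y[:2] = [0, 1]
            roc = roc_curve(x, y)
            cutoff, j = youden_cutoff(roc)
            # brute force over every candidate cutoff (all midpoints + extremes)
            best = -np.inf
            for t in np.concatenate([[x.min() - 1], (np.sort(np.unique(x))[:-1] + np.sort(np.unique(x))[1:]) / 2, [x.max() + 1]]):
                cm = confusion_at(x, y, t)
                best = max(best, cm.sensitivity + cm.specificity - 1)
            assert j == pytest.approx(best, abs=1e-12)
            cm = confusion_at(x, y, cutoff)
            assert cm.sensitivity + cm.specificity - 1 == pytest.approx(j, abs=1e-12)


class TestConfusion:
    def test_perfect_split(self):
        cm = confusion_at([1, 2, 9, 10], [0, 0, 1, 1], 5.0)
        assert (cm.sensitivity, cm.specificity) == (1.0, 1.0)

    def test_hand_enumerated_toy(self):
        # indices >= 6 called positive: subjects (7,1) (5,1) (9,1) (2,0) (6,0) (3,0)
        cm = confusion_at([7, 5, 9, 2, 6, 3], [1, 1, 1, 0, 0, 0], 6.0)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)
        assert cm.sensitivity == pytest.approx(2 / 3)
        assert cm.specificity == pytest.approx(2 / 3)

    def test_cutoff_below_everything(self):
        cm = confusion_at([1, 2, 9, 10], [0, 0, 1, 1], -100.0)
        assert (cm.sensitivity, cm.specificity) == (1.0, 0.0)

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            confusion_at([1, 2], [0, 1], np.inf)


class TestTwoProportionZ:
    def test_equal_proportions_z_zero(self):
        res = two_proportion_ztest(10, 50, 20, 100)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_z_squared_equals_pearson_chi2(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(5, 200, size=2)
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            z = two_proportion_ztest(x1, n1, x2, n2).statistic
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2 = chi_square(table).statistic
            assert z**2 == pytest.approx(chi2, abs=1e-10)

    def test_antisymmetry(self):
        a = two_proportion_ztest(30, 100, 10, 80)
        b = two_proportion_ztest(10, 80, 30, 100)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        res = two_proportion_ztest(0, 10, 0, 20)
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        z_ref, p_ref = proportions_ztest([30, 12], [100, 90])
        res = two_proportion_ztest(30, 100, 12, 90)
        assert res.statistic == pytest.approx(z_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)


class TestWelch:
    def test_identical_samples(self):
        res = welch_ttest([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_equal_variance_balanced_matches_pooled_t(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        welch = welch_ttest(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        # balanced design with equal sample variance estimates differ only via df
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 25)
        t1 = welch_ttest(a, b).statistic
        t2 = welch_ttest(7.3 * a, 7.3 * b).statistic
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [2.0, 3.0])


class TestChiSquare:
    def test_independent_table_statistic_zero(self):
        table = np.outer([30, 70], [0.4, 0.6]) * 1  # exact independence
        res = chi_square(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # margins 30/30; expected 15 everywhere; chi2 = 4 * 25/15 = 20/3
        res = chi_square([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3, abs=1e-10)
        assert res.df == 1

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 50, size=(3, 4))
        base = chi_square(table).statistic
        assert chi_square(table[::-1]).statistic == pytest.approx(base)
        assert chi_square(table[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 10]])


class TestStratifiedKFold:
    def test_balanced_divisible_case(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(y, 5, seed=0)
        for f in range(5):
            assert (y[folds == f] == 0).sum() == 10
            assert (y[folds == f] == 1).sum() == 10

    def test_cohort_sized_case(self):
        y = np.array([1] * 136 + [0] * 50)
        folds = stratified_kfold(y, 5, seed=1)
        hcc_counts = sorted((y[folds == f] == 1).sum() for f in range(5))
        healthy_counts = [(y[folds == f] == 0).sum() for f in range(5)]
        assert hcc_counts == [27, 27, 27, 27, 28]
        assert healthy_counts == [10] * 5

    def test_partition_property(self, rng):
        y = rng.integers(0, 2, size=73)
        y[:10] = 1
        y[10:20] = 0
        folds = stratified_kfold(y, 5, seed=2)
        assert folds.shape == y.shape
        assert set(folds) == set(range(5))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([0, 0, 0, 1, 1], 3, seed=0)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        # class ratio 1:3 -> intercept = ln(1/3)
        y = np.array([1] * 25 + [0] * 75)
        X = np.zeros((100, 1))
        fit = fit_logistic_irls(X, y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(200, 2))
        y = (X @ [1.0, -0.5] + rng.normal(scale=0.8, size=200) > 0).astype(int)
        fit = fit_logistic_irls(X, y)
        ref = LogisticRegression(C=1e8, tol=1e-10, max_iter=1000).fit(X, y)
        assert fit.coef[0] == pytest.approx(ref.intercept_[0], abs=1e-4)
        assert fit.coef[1:] == pytest.approx(ref.coef_[0], abs=1e-4)

    def test_separable_data_flagged_and_cv_auc_near_one(self, rng):
        y = rng.integers(0, 2, size=100)
        x = y + rng.normal(scale=1e-3, size=100)
        fit = fit_logistic_irls(x[:, None], y)
        assert fit.separated or fit.coef[1] > 10
        report = logistic_cv(x, y, k=5, seed=0)
        assert report.mean_auc > 0.99

    def test_permuted_labels_cv_auc_near_half(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=150)
        aucs = []
        for seed in range(20):
            y = rng.permutation([0] * 75 + [1] * 75)
            aucs.append(logistic_cv(x, y, k=5, seed=seed).mean_auc)
        # null mean AUC is 0.5; 20-replicate average within ~3 sd of the null
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_standardization_frozen_from_training_fold(self, rng):
        # shifting/scaling features leaves CV metrics unchanged
        x = rng.normal(size=120)
        y = (x + rng.normal(scale=1.0, size=120) > 0).astype(int)
        a = logistic_cv(x, y, k=5, seed=3)
        b = logistic_cv(1000.0 + 50.0 * x, y, k=5, seed=3)
        assert a.fold_auc == pytest.approx(b.fold_auc, abs=1e-9)
        assert a.fold_accuracy == pytest.approx(b.fold_accuracy, abs=1e-9)


class TestEvaluateCohort:
    def test_full_report_structure_and_consistency(self):
        df = simulate_cohort(CohortSpec(), seed=12)
        rep = evaluate_cohort(df, cv_seed=12)
        cm = rep["confusion"]
        assert cm["tp"] + cm["fn"] == rep["n_hcc"]
        assert cm["tn"] + cm["fp"] == rep["n_healthy"]
        assert 0.0 <= rep["auc"] <= 1.0
        assert rep["sensitivity"] + rep["specificity"] - 1 == pytest.approx(rep["youden_j"])

    def test_fixed_cutoff_respected(self):
        df = simulate_cohort(CohortSpec(), seed=13)
        rep = evaluate_cohort(df, cutoff=6.0)
        assert rep["cutoff"] == 6.0
        idx = derive_index(df)
        manual = confusion_at(idx, (df["group"] == "hcc").astype(int), 6.0)
        assert rep["sensitivity"] == pytest.approx(manual.sensitivity)
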