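import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdmri._svm import HAVE_LOWLEVEL, PrecomputedSVM, loo_accuracy, sigmoid_kernel
from pdmri.discriminate import (
    METRIC_ORDER,
    FoldResult,
    SelectionResult,
    SvmGrid,
    _run_fold,
    bundles_to_frame,
    confusion_metrics,
    frame_to_bundles,
    fuse,
    grid_search_svm,
    loocv,
    roc_auc,
    select_features,
    selection_frequency,
    standardize,
    two_sample_t,
)


def mann_whitney_auc(scores, is_case):
    """Brute-force AUC: pairwise comparisons with ties counted 1/2."""
    pos = scores[is_case]
    neg = scores[~is_case]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTwoSampleT:
    def test_matches_scipy_pooled(self, rng):
        a, b = rng.normal(size=(2, 15))
        t, p = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sign_convention_cases_higher_positive(self, rng):
        t, _ = two_sample_t(rng.normal(5, 1, 20), rng.normal(0, 1, 20))
        assert t > 0

    def test_zero_variance_degenerate(self):
        assert two_sample_t(np.ones(5), np.ones(6)) == (0.0, 1.0)

    def test_ranksum_matches_scipy(self, rng):
        a, b = rng.normal(size=(2, 12))
        t, p = two_sample_t(a, b, method="ranksum")
        ref = stats.ranksums(a, b)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(np.array([1.0]), np.array([0.0, 1.0]))


class TestSelectFeatures:
    def test_strong_effect_selected(self, rng, bundle_factory):
        bundles = bundle_factory(12, 12, 20, rng, effects=[("ALFF", 5, 3.0)])
        sel = select_features(bundles)
        assert 5 in sel.indices("ALFF")

    def test_null_type_one_rate_close_to_alpha(self, bundle_factory):
        # with no real effect, ~alpha of features pass by chance
        rng = np.random.default_rng(2024)
        total = kept = 0
        for _ in range(40):
            bundles = bundle_factory(10, 12, 30, rng, metrics=("ALFF",))
            sel = select_features(bundles)
            kept += len(sel.indices("ALFF"))
            total += 30
        rate = kept / total
        assert 0.02 < rate < 0.09

    def test_bonferroni_stricter(self, rng, bundle_factory):
        bundles = bundle_factory(10, 10, 50, rng, effects=[("GM", 0, 1.0)])
        plain = select_features(bundles).total
        corrected = select_features(bundles, correction="bonferroni").total
        assert corrected <= plain

    def test_all_null_keeps_single_fallback(self, bundle_factory):
        rng = np.random.default_rng(99)
        # constant features cannot pass; fallback keeps exactly one
        bundles = bundle_factory(5, 5, 4, rng, metrics=("ALFF",))
        for b in bundles:
            b.features["ALFF"] = np.zeros(4)
            b.features["ALFF"][0] = 1.0 if b.group == "case" else 1.0
        bundles[0].features["ALFF"][1] = 1e-9  # minuscule, non-significant
        with pytest.warns(UserWarning, match="no feature passed"):
            sel = select_features(bundles)
        assert sel.total == 1

    def test_selection_matches_scalar_tests(self, rng, bundle_factory):
        bundles = bundle_factory(8, 9, 15, rng)
        sel = select_features(bundles, alpha=0.3)
        case = [b for b in bundles if b.group == "case"]
        ctrl = [b for b in bundles if b.group == "control"]
        for m in METRIC_ORDER:
            expected = []
            for j in range(15):
                t, p = two_sample_t(
                    np.array([b.features[m][j] for b in case]),
                    np.array([b.features[m][j] for b in ctrl]))
                if p < 0.3:
                    expected.append(j)
            assert sel.indices(m) == expected


class TestFuseAndStandardize:
    def test_fixed_metric_order(self, rng, bundle_factory):
        bundles = bundle_factory(3, 3, 10, rng)
        sel = SelectionResult(per_metric={
            "ALFF": [(2, 0.0, 0.0)], "ReHo": [(7, 0.0, 0.0)],
            "CSF": [(0, 0.0, 0.0), (1, 0.0, 0.0)]}, alpha=0.05)
        fused = fuse(bundles[0], sel)
        f = bundles[0].features
        expected = np.array([f["ReHo"][7], f["ALFF"][2], f["CSF"][0],
                             f["CSF"][1]])
        np.testing.assert_array_equal(fused, expected)

    def test_standardize_train_stats(self, rng):
        X = rng.normal(3.0, 2.0, size=(20, 6))
        scaled, _, means, sds = standardize(X)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(means, X.mean(axis=0))

    def test_test_row_uses_training_parameters(self, rng):
        X = rng.normal(size=(10, 4))
        x = rng.normal(size=4)
        _, scaled_x, means, sds = standardize(X, x)
        np.testing.assert_allclose(scaled_x[0], (x - means) / sds, atol=1e-12)

    def test_constant_feature_clamped(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="clamped"):
            scaled, _, _, sds = standardize(X)
        assert sds[1] == 1.0
        np.testing.assert_allclose(scaled[:, 1], 0.0)


class TestSvmWrapper:
    def test_matches_public_svc(self, rng):
        from sklearn.svm import SVC
        for _ in range(10):
            X = rng.normal(size=(14, 5))
            y = np.where(rng.random(14) < 0.5, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            g, c = 0.5, 2.0
            K = sigmoid_kernel(X @ X.T, g)
            model = PrecomputedSVM(C=c).fit(K, y)
            svc = SVC(C=c, kernel="sigmoid", gamma=g, coef0=0.0).fit(X, y)
            Kt = sigmoid_kernel(X @ X.T, g)
            np.testing.assert_allclose(model.decision(Kt),
                                       svc.decision_function(X), atol=1e-8)

    def test_loo_accuracy_matches_manual(self, rng):
        from sklearn.svm import SVC
        X = rng.normal(size=(12, 4))
        y = np.array([1.0] * 6 + [-1.0] * 6)
        g, c = 1.0, 4.0
        K = sigmoid_kernel(X @ X.T, g)
        fast = loo_accuracy(K, y, c)
        correct = 0
        for i in range(12):
            keep = np.arange(12) != i
            svc = SVC(C=c, kernel="precomputed").fit(K[np.ix_(keep, keep)],
                                                     y[keep])
            correct += svc.predict(K[i, keep][None, :])[0] == y[i]
        assert fast == pytest.approx(correct / 12)

    def test_single_class_rejected(self, rng):
        K = np.eye(5)
        with pytest.raises(ValueError, match="single class"):
            PrecomputedSVM().fit(K, np.ones(5))

    def test_lowlevel_binding_available(self):
        # the fast path should exist in a standard scikit-learn install;
        # the public-API fallback keeps the package working if it ever moves
        assert HAVE_LOWLEVEL


class TestGridSearch:
    def test_grid_cardinality(self):
        grid = SvmGrid()
        assert grid.n_pairs == 441
        assert grid.c_values[0] == 2.0**-10
        assert grid.c_values[-1] == 2.0**10
        assert len(grid.g_values) == 21

    def test_separable_data_perfect_inner_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(8, 3)) + 4,
                       rng.normal(0, 0.3, size=(8, 3)) - 4])
        y = np.array([1.0] * 8 + [-1.0] * 8)
        grid = SvmGrid(c_exponents=tuple(range(-3, 4)),
                       g_exponents=tuple(range(-3, 4)))
        _, c, g, inner = grid_search_svm(X, y, grid)
        assert inner == 1.0

    def test_tie_break_smallest_c_then_g(self, rng):
        # strongly separable data: many pairs reach accuracy 1; the winner
        # must be the first in (C, G) lexicographic order among them
        X = np.vstack([np.full((5, 2), 3.0), np.full((5, 2), -3.0)])
        X += rng.normal(0, 0.05, size=X.shape)
        y = np.array([1.0] * 5 + [-1.0] * 5)
        grid = SvmGrid(c_exponents=(-2, 0, 2), g_exponents=(-2, 0, 2))
        _, c, g, inner = grid_search_svm(X, y, grid)
        acc = np.zeros((3, 3))
        for jc, ce in enumerate((-2, 0, 2)):
            for jg, ge in enumerate((-2, 0, 2)):
                K = sigmoid_kernel(X @ X.T, 2.0**ge)
                acc[jc, jg] = loo_accuracy(K, y, 2.0**ce)
        jc, jg = np.unravel_index(np.argmax(acc), acc.shape)
        assert (c, g) == (2.0**((-2, 0, 2)[jc]), 2.0**((-2, 0, 2)[jg]))


class TestLoocv:
    def test_fold_count_and_exclusivity(self, rng, bundle_factory):
        bundles = bundle_factory(5, 6, 8, rng, effects=[("ReHo", 1, 4.0)])
        grid = SvmGrid(c_exponents=(-2, 0, 2), g_exponents=(-2, 0, 2))
        summary, folds = loocv(bundles, grid=grid)
        assert summary.n_folds == 11
        assert [f.held_out for f in folds] == [b.subject_id for b in bundles]
        assert set(summary.fold_counts.columns) >= set(METRIC_ORDER)

    def test_strong_effects_classified_well(self, rng, bundle_factory):
        bundles = bundle_factory(8, 8, 10, rng,
                                 effects=[("ALFF", 0, 4.0), ("GM", 3, 4.0)])
        grid = SvmGrid(c_exponents=(-4, -2, 0, 2, 4),
                       g_exponents=(-4, -2, 0, 2, 4))
        summary, _ = loocv(bundles, grid=grid)
        assert summary.accuracy >= 80.0

    def test_no_leakage_held_out_features_irrelevant(self, rng, bundle_factory):
        """Perturbing the held-out subject's features must not change the
        fitted fold in any way except through its own test row."""
        bundles = bundle_factory(6, 6, 8, rng, effects=[("WM", 2, 3.0)])
        grid = SvmGrid(c_exponents=(-2, 0, 2), g_exponents=(-2, 0, 2))
        train, held = bundles[1:], bundles[0]
        fold_a = _run_fold(train, held, alpha=0.05, grid=grid,
                           metrics=METRIC_ORDER, selector="t")
        # same training set, identical held-out features -> identical fold
        fold_b = _run_fold(train, held, alpha=0.05, grid=grid,
                           metrics=METRIC_ORDER, selector="t")
        assert fold_a.index_score == fold_b.index_score
        # a *different* held-out subject against the same training set gets
        # the same selection, C and G: the fit ignores the held-out data
        import copy
        held2 = copy.deepcopy(held)
        for m in METRIC_ORDER:
            held2.features[m] = held2.features[m] + 100.0
        fold_c = _run_fold(train, held2, alpha=0.05, grid=grid,
                           metrics=METRIC_ORDER, selector="t")
        assert fold_c.selection.per_metric == fold_a.selection.per_metric
        assert (fold_c.C, fold_c.G) == (fold_a.C, fold_a.G)
        assert fold_c.inner_accuracy == fold_a.inner_accuracy

    def test_global_mode_fixes_cg(self, rng, bundle_factory):
        bundles = bundle_factory(5, 5, 6, rng, effects=[("CSF", 0, 3.0)])
        grid = SvmGrid(c_exponents=(-2, 0, 2), g_exponents=(-2, 0, 2))
        summary, folds = loocv(bundles, grid=grid, mode="global")
        assert summary.mode == "global"
        assert len({(f.C, f.G) for f in folds}) == 1

    def test_too_few_subjects_rejected(self, rng, bundle_factory):
        bundles = bundle_factory(1, 5, 4, rng)
        with pytest.raises(ValueError, match="at least 2"):
            loocv(bundles)

    def test_metric_subset(self, rng, bundle_factory):
        bundles = bundle_factory(5, 5, 6, rng, effects=[("ALFF", 1, 4.0)])
        grid = SvmGrid(c_exponents=(0,), g_exponents=(0,))
        summary, folds = loocv(bundles, grid=grid, metrics=("ALFF", "RFCS"))
        assert set(folds[0].selection.per_metric) <= {"ALFF", "RFCS"}


class TestConfusionMetrics:
    @staticmethod
    def _folds(tp, fn, tn, fp):
        mk = lambda truth, pred: FoldResult(
            held_out="x", selection=SelectionResult({}, 0.05), C=1, G=1,
            inner_accuracy=1.0, index_score=0.0, predicted=pred, truth=truth)
        return ([mk("case", "case")] * tp + [mk("case", "control")] * fn +
                [mk("control", "control")] * tn + [mk("control", "case")] * fp)

    def test_worked_example(self):
        # 19 cases / 27 controls with 4 + 2 errors
        acc, sens, spec = confusion_metrics(self._folds(15, 4, 25, 2))
        assert acc == pytest.approx(100 * 40 / 46)
        assert sens == pytest.approx(100 * 15 / 19)
        assert spec == pytest.approx(100 * 25 / 27)

    def test_perfect(self):
        assert confusion_metrics(self._folds(3, 0, 4, 0)) == (100.0, 100.0,
                                                              100.0)

    def test_missing_class_nan(self):
        with pytest.warns(UserWarning, match="missing"):
            acc, sens, spec = confusion_metrics(self._folds(0, 0, 4, 1))
        assert np.isnan(sens)
        assert spec == pytest.approx(80.0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        is_case = np.array([False, False, True, True])
        fpr, tpr, _, auc = roc_auc(scores, is_case)
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_reversed_scores_auc_zero(self):
        auc = roc_auc(np.array([2.0, 1.0, -1.0, -2.0]),
                      np.array([False, False, True, True]))[3]
        assert auc == 0.0

    def test_matches_mann_whitney_500_sets(self):
        rng = np.random.default_rng(31415)
        for _ in range(500):
            n_pos = int(rng.integers(2, 12))
            n_neg = int(rng.integers(2, 12))
            scores = rng.normal(size=n_pos + n_neg)
            if rng.random() < 0.3:  # force ties
                scores = np.round(scores, 0)
            is_case = np.array([True] * n_pos + [False] * n_neg)
            auc = roc_auc(scores, is_case)[3]
            assert auc == pytest.approx(mann_whitney_auc(scores, is_case),
                                        abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))


class TestSelectionFrequency:
    @staticmethod
    def _fold_with(per_metric):
        return FoldResult(held_out="x",
                          selection=SelectionResult(per_metric, 0.05),
                          C=1, G=1, inner_accuracy=1.0, index_score=0.0,
                          predicted="case", truth="case")

    def test_strictly_greater_than_min_count(self, rng, bundle_factory):
        bundles = bundle_factory(4, 4, 6, rng, effects=[("ALFF", 2, 5.0)])
        folds = [self._fold_with({"ALFF": [(2, 5.0, 0.001)]})] * 24 \
            + [self._fold_with({"ALFF": [(1, 2.0, 0.04)]})] * 23
        df = selection_frequency(folds, bundles, min_count=23)
        assert list(df["RegionIndex"]) == [2]  # 24 > 23 in; 23 == 23 out
        assert df.loc[0, "Count"] == 24
        assert df.loc[0, "Type"] == "ALFF"

    def test_statistics_recomputed_on_whole_cohort(self, rng, bundle_factory):
        bundles = bundle_factory(6, 6, 4, rng, effects=[("GM", 1, 4.0)])
        folds = [self._fold_with({"GM": [(1, 0.0, 0.5)]})] * 30
        df = selection_frequency(folds, bundles, min_count=23)
        case = np.array([b.features["GM"][1] for b in bundles
                         if b.group == "case"])
        ctrl = np.array([b.features["GM"][1] for b in bundles
                         if b.group == "control"])
        t, p = two_sample_t(case, ctrl)
        assert df.loc[0, "T-value"] == pytest.approx(t)
        assert df.loc[0, "P-value"] == pytest.approx(p)

    def test_region_names_resolved(self, rng, bundle_factory):
        bundles = bundle_factory(4, 4, 3, rng)
        folds = [self._fold_with({"ReHo": [(0, 1.0, 0.01)]})] * 25
        df = selection_frequency(folds, bundles, min_count=23,
                                 region_names=["A", "B", "C"])
        assert df.loc[0, "Region"] == "A"


class TestFrameRoundtrip:
    def test_bundles_frame_bundles(self, rng, bundle_factory):
        bundles = bundle_factory(3, 4, 5, rng)
        frame = bundles_to_frame(bundles)
        back = frame_to_bundles(frame)
        assert [b.subject_id for b in back] == [b.subject_id for b in bundles]
        for a, b in zip(bundles, back):
            assert a.group == b.group
            for m in METRIC_ORDER:
                np.testing.assert_allclose(a.features[m], b.features[m])

    def test_csv_roundtrip(self, rng, bundle_factory, tmp_path):
        bundles = bundle_factory(2, 2, 3, rng)
        path = tmp_path / "features.csv"
        bundles_to_frame(bundles).to_csv(path, index=False)
        back = frame_to_bundles(pd.read_csv(path))
        np.testing.assert_allclose(back[0].features["ALFF"],
                                   bundles[0].features["ALFF"], atol=1e-12)
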