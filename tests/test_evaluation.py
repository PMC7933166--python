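"""ROC machinery against brute-force oracles, operating points, harmonic
means, cross-validation contracts, and the report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from painsignal import (
    CohortConfig,
    ConfigurationError,
    ModelSpec,
    ResampleConfig,
    RocUndefinedError,
    StratificationError,
    auroc,
    binarize_cpot,
    build_dataset,
    default_model_specs,
    evaluate,
    feature_importance_report,
    generate_cohort,
    harmonic_mean,
    harmonic_mean_3,
    operating_point_table,
    optimal_operating_point,
    preprocess_cohort,
    prevalence,
    roc_curve,
    split_and_crossvalidate,
)


def mann_whitney_auroc(scores, labels):
    """Brute-force pairwise oracle: P(score+ > score-) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestBinarizeCpot:
    @pytest.mark.parametrize("score,label", [(0, 0), (2, 0), (3, 1), (8, 1)])
    def test_threshold_at_three(self, score, label):
        assert binarize_cpot(score) == label

    @pytest.mark.parametrize("score", [-1, 9])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            binarize_cpot(score)


class TestPrevalence:
    def test_study_scale_worked_example(self):
        assert round(prevalence(3925, 117190), 1) == 3.3

    def test_edge_cases(self):
        assert prevalence(0, 50) == 0.0
        assert prevalence(50, 50) == 100.0

    def test_errors(self):
        with pytest.raises(ValueError):
            prevalence(1, 0)
        with pytest.raises(ValueError):
            prevalence(5, 3)


class TestRocCurve:
    def test_fixture_matches_exhaustive_sweep(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        curve = roc_curve(scores, labels)
        # brute-force threshold sweep over the distinct scores
        for thr, sens, spec in zip(curve.thresholds[1:], curve.sensitivity[1:],
                                   curve.specificity[1:]):
            pred = scores >= thr
            assert sens == pytest.approx(pred[labels == 1].mean())
            assert spec == pytest.approx((~pred)[labels == 0].mean())
        assert curve.sensitivity[0] == 0.0 and curve.specificity[0] == 1.0
        assert curve.sensitivity[-1] == 1.0 and curve.specificity[-1] == 0.0

    def test_all_scores_equal_two_point_diagonal(self):
        curve = roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert len(curve.thresholds) == 2
        assert auroc(curve) == pytest.approx(0.5)

    def test_perfect_separation_hits_corner(self):
        curve = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert any(s == 1.0 and p == 1.0
                   for s, p in zip(curve.sensitivity, curve.specificity))
        assert auroc(curve) == pytest.approx(1.0)

    def test_single_class_undefined(self):
        with pytest.raises(RocUndefinedError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_monotone_sensitivity(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=100).round(1)
        y = rng.integers(0, 2, 100)
        curve = roc_curve(s, y)
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.specificity) <= 0).all()


class TestAuroc:
    def test_fixture_value(self):
        curve = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auroc(curve) == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_equals_mann_whitney_on_random_fixtures(self, seed):
        """Trapezoidal AUROC == pairwise Mann-Whitney statistic, with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = rng.normal(size=n).round(1)        # coarse grid forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:max(1, n // 3)]] = 1
        if labels.sum() in (0, n):
            return
        got = auroc(roc_curve(scores, labels))
        assert got == pytest.approx(mann_whitney_auroc(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_score_negation_reflects_auroc(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=80).round(1)
        y = rng.integers(0, 2, 80)
        a = auroc(roc_curve(s, y))
        assert auroc(roc_curve(-s, y)) == pytest.approx(1.0 - a, abs=1e-12)

    def test_label_permutation_null_centered_at_half(self):
        """95% of label permutations give AUROC within 0.5 +/- 2 SE."""
        rng = np.random.default_rng(11)
        n, n1 = 200, 50
        scores = rng.normal(size=n)
        ranks = rankdata(scores)
        se = np.sqrt((n + 1) / (12 * n1 * (n - n1)))
        inside = 0
        for _ in range(1000):
            pos = rng.permutation(n)[:n1]
            a = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * (n - n1))
            inside += abs(a - 0.5) <= 2 * se
        assert 0.92 <= inside / 1000 <= 0.99


class TestHarmonicMean:
    def test_identities(self):
        assert harmonic_mean(1.0, 1.0) == 1.0
        assert harmonic_mean(0.63, 0.63) == pytest.approx(0.63)

    def test_table_optimal_point_value(self):
        assert round(harmonic_mean(0.736, 0.807), 3) == 0.770

    def test_zero_by_continuity(self):
        assert harmonic_mean(0.0, 0.9) == 0.0

    def test_three_way_variant(self):
        assert harmonic_mean_3(1.0, 1.0, 1.0) == 1.0
        assert harmonic_mean_3(0.5, 0.5, 0.5) == pytest.approx(0.5)
        assert harmonic_mean_3(0.0, 0.5, 0.5) == 0.0


class TestOperatingPoints:
    def test_perfect_scorer_reports_ones(self):
        curve = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        for row in operating_point_table(curve):
            assert row.achieved
            if row.condition.startswith("sensitivity"):
                assert row.point.specificity == 1.0
            else:
                assert row.point.sensitivity == 1.0

    def test_random_scorer_complementary_coordinates(self):
        rng = np.random.default_rng(21)
        n = 4000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        curve = roc_curve(scores, labels)
        table = {r.condition: r.point for r in operating_point_table(curve)}
        assert table["sensitivity>=0.6"].specificity == pytest.approx(0.4, abs=0.05)
        assert table["specificity>=0.8"].sensitivity == pytest.approx(0.2, abs=0.05)

    def test_matches_exhaustive_threshold_audit(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(size=300).round(1)
        labels = (rng.random(300) < 0.3).astype(int)
        curve = roc_curve(scores, labels)
        table = operating_point_table(curve)

        thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
        audit = []
        for t in thresholds:
            pred = scores >= t
            audit.append((t, pred[labels == 1].mean(), (~pred)[labels == 0].mean()))
        for row in table:
            target = float(row.condition.split(">=")[1])
            axis = 1 if row.condition.startswith("sensitivity") else 2
            other = 2 if axis == 1 else 1
            cands = [a for a in audit if a[axis] >= target]
            best = min(cands, key=lambda a: (a[axis], -a[other]))
            assert row.point.sensitivity == pytest.approx(best[1])
            assert row.point.specificity == pytest.approx(best[2])
            assert row.point.threshold == pytest.approx(best[0])

    def test_unreachable_target_flagged(self):
        curve = roc_curve([0.2, 0.2, 0.8], [0, 1, 1])
        rows = operating_point_table(curve, sens_targets=(1.5,), spec_targets=())
        assert not rows[0].achieved

    def test_optimal_point_maximizes_harmonic_mean(self):
        rng = np.random.default_rng(23)
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(1.5, 1, 2000)])
        labels = np.array([0] * 2000 + [1] * 2000)
        curve = roc_curve(scores, labels)
        opt = optimal_operating_point(curve)
        hm = harmonic_mean(opt.sensitivity, opt.specificity)
        for _, s, p in curve.vertices():
            assert hm >= harmonic_mean(s, p) - 1e-12
        # symmetric binormal scorer with equal class sizes: the optimum sits
        # near the equal-sensitivity/specificity point
        assert abs(opt.sensitivity - opt.specificity) < 0.1

    def test_perfect_scorer_optimum_is_corner(self):
        curve = roc_curve([0.1, 0.9], [0, 1])
        opt = optimal_operating_point(curve)
        assert (opt.sensitivity, opt.specificity) == (1.0, 1.0)


class TestFeatureImportances:
    def test_normalized_and_ranked(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(31)
        X = rng.normal(size=(200, 3))
        y = (X[:, 1] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        report = feature_importance_report(rf, ["a", "b", "c"])
        total = sum(v for _, v in report)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert report[0][0] == "b"
        assert [v for _, v in report] == sorted((v for _, v in report), reverse=True)

    def test_non_forest_rejected(self):
        from sklearn.linear_model import LogisticRegression

        with pytest.raises(TypeError):
            feature_importance_report(LogisticRegression(), ["a"])


class TestModelSpec:
    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("random_forest", {})

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("perceptron", {"lr": [0.1]})

    def test_defaults_pin_study_hyperparameters(self):
        fams = {m.family: m for m in default_model_specs()}
        assert fams["svm_rbf"].grid["C"] == [10.0]
        assert fams["svm_rbf"].grid["gamma"] == [10.0]
        assert fams["random_forest"].grid["max_depth"] == [14]
        assert fams["random_forest"].grid["n_estimators"] == [17]
        assert fams["logistic_regression"].grid["C"] == [1.0]


def _toy_dataset(n=100, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    logits = 2.0 * X[:, 0] if informative else np.zeros(n)
    y = (logits + rng.normal(0, 1, n) > 0.8).astype(int)
    if y.sum() < 12:            # keep folds stratifiable
        y[rng.permutation(n)[:12]] = 1
    return X, y


class TestSplitAndCrossvalidate:
    def test_nine_to_one_split_size(self):
        X, y = _toy_dataset(100, seed=1)
        res = split_and_crossvalidate((X, y), default_model_specs()[2], seed=0,
                                      resample_cfg=None)
        assert len(res.test_labels) == 10
        assert len(res.train_labels) == 90

    def test_degenerate_grid_selected_directly(self):
        X, y = _toy_dataset(100, seed=2)
        spec = ModelSpec("logistic_regression", {"C": [0.7], "tol": [1e-4]})
        res = split_and_crossvalidate((X, y), spec, seed=0, resample_cfg=None)
        assert res.model_spec.selected == {"C": 0.7, "tol": 1e-4}

    def test_grid_search_picks_better_point(self):
        X, y = _toy_dataset(300, seed=3)
        spec = ModelSpec("logistic_regression", {"C": [1e-6, 1.0], "tol": [1e-4]})
        res = split_and_crossvalidate((X, y), spec, seed=0,
                                      resample_cfg=ResampleConfig(seed=0),
                                      grid_folds=5)
        assert res.model_spec.selected["C"] == 1.0

    def test_test_rows_untouched_by_oversampling(self):
        X, y = _toy_dataset(100, seed=4)
        res = split_and_crossvalidate((X, y), default_model_specs()[0], seed=1,
                                      resample_cfg=ResampleConfig(seed=1))
        np.testing.assert_array_equal(res.test_labels, y[res.test_index])
        assert len(res.test_labels) == 10

    def test_single_class_raises_stratification_error(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(StratificationError):
            split_and_crossvalidate((X, np.zeros(20, dtype=int)),
                                    default_model_specs()[0], seed=0)


class TestEvaluate:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_dataset():
        cohort = generate_cohort(CohortConfig(n_patients=60, seed=8))
        return build_dataset(preprocess_cohort(cohort))

    def test_report_structure_and_determinism(self, small_dataset):
        rep1 = evaluate(small_dataset, seed=3, n_folds=5)
        rep2 = evaluate(small_dataset, seed=3, n_folds=5)
        assert rep1.to_dict() == rep2.to_dict()
        assert set(rep1.models) == {"random_forest", "svm_rbf", "logistic_regression"}
        for r in rep1.models.values():
            assert 0.0 <= r.test_auroc <= 1.0
            assert len(r.fold_test_aurocs) <= 5
        imp = rep1.models["random_forest"].feature_importances
        assert sum(v for _, v in imp) == pytest.approx(1.0, abs=1e-9)

    def test_prevalence_reported_on_percent_scale(self, small_dataset):
        rep = evaluate(small_dataset, seed=3, n_folds=5)
        assert rep.prevalence_percent == pytest.approx(
            100.0 * small_dataset.y.mean())

    def test_assessment_level_split_available(self, small_dataset):
        rep = evaluate(small_dataset, seed=3, n_folds=5, split_unit="assessment")
        assert 0.0 <= rep.models["random_forest"].test_auroc <= 1.0

    def test_too_few_positives_raises(self):
        X, y = _toy_dataset(40, seed=5)
        y[:] = 0
        y[:3] = 1
        with pytest.raises(StratificationError):
            evaluate((X, y), seed=0, n_folds=10)
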