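import numpy as np
import pandas as pd
import pytest

from limbid.identify import (
    ScoreSet,
    accumulate_days,
    confusion,
    cross_validated_accuracy,
    cross_validated_scores,
    fit_accuracy_asymptote,
    iter_folds,
    make_classifier,
    make_fold_plan,
    roc_open_set,
    scalability_curve,
    train_and_score,
)
from limbid.synth import simulate_study


def brute_force_roc(genuine, impostor):
    """O(n^2) threshold enumeration oracle for EER (%) and AUC."""
    thr = sorted(set(list(genuine) + list(impostor)))
    thr = [thr[0] - 1.0] + thr + [thr[-1] + 1.0]
    far = [sum(s >= t for s in impostor) / len(impostor) for t in thr]
    frr = [sum(s < t for s in genuine) / len(genuine) for t in thr]
    eer = None
    for k in range(len(thr)):
        d = far[k] - frr[k]
        if d == 0:
            eer = far[k]
            break
        if d < 0:
            d1 = far[k - 1] - frr[k - 1]
            lam = d1 / (d1 - d)
            eer = far[k - 1] + lam * (far[k] - far[k - 1])
            break
    pts = sorted(zip(far, [1 - f for f in frr]))
    auc = sum(
        (x2 - x1) * (y1 + y2) / 2 for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:])
    )
    return eer * 100.0, auc


class TestFoldPlan:
    def test_one_fold_per_day_and_no_leakage(self):
        data, _ = simulate_study(3, 5, 2, seed=0)
        plan = make_fold_plan(data)
        assert plan.n_folds == 5
        for train, test in iter_folds(data, plan):
            test_days = set(data.meta.day_index.iloc[test])
            assert len(test_days) == 1
            assert not test_days & set(data.meta.day_index.iloc[train])

    def test_plan_is_determined_by_day_labels_alone(self):
        data, _ = simulate_study(3, 4, 2, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(data.n_sessions)
        shuffled = data.subset(np.ones(data.n_sessions, dtype=bool))
        shuffled.channels = shuffled.channels[perm]
        shuffled.meta = shuffled.meta.iloc[perm].reset_index(drop=True)
        assert make_fold_plan(shuffled) == make_fold_plan(data)

    def test_single_day_rejected(self):
        data, _ = simulate_study(3, 1, 4, seed=0)
        with pytest.raises(ValueError):
            make_fold_plan(data)


class TestAccumulateDays:
    def test_full_range_is_identity(self):
        data, _ = simulate_study(3, 5, 2, seed=1)
        np.testing.assert_array_equal(accumulate_days(data, 5).channels, data.channels)

    def test_first_d_day_labels_kept_and_counts_conserved(self):
        data, _ = simulate_study(3, 5, 2, seed=1)
        sub = accumulate_days(data, 2)
        assert set(sub.meta.day_index) == {1, 2}
        per_day = data.meta.groupby("day_index").size()
        assert sub.n_sessions == per_day.loc[[1, 2]].sum()

    def test_out_of_range_rejected(self):
        data, _ = simulate_study(3, 5, 2, seed=1)
        for d in (1, 6):
            with pytest.raises(ValueError):
                accumulate_days(data, d)


class TestTrainAndScore:
    def test_lda_on_separable_subjects_is_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(5, 0.1, (20, 5))])
        y = np.repeat(["A", "B"], 20)
        clf = make_classifier("lda")
        scores = train_and_score(clf, X, y, X, y)
        assert scores.accuracy == 100.0

    def test_knn_duplicate_test_point_gets_train_label(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [4.0, 4.0], [5.0, 5.0]])
        y = np.array(["A", "A", "B", "B"])
        scores = train_and_score(make_classifier("knn"), X, y, X[[1, 2]], y[[1, 2]])
        np.testing.assert_array_equal(scores.y_pred, ["A", "B"])

    def test_rf_beats_chance_on_generator_defaults(self):
        data, _ = simulate_study(10, 3, 4, seed=5)
        acc = cross_validated_accuracy(data, "limb", "rf", seed=0)
        assert acc > 50.0  # chance is 10%

    def test_unenrolled_class_scored_and_counted_as_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = np.repeat(["A", "B", "C"], 10)
        scores = train_and_score(
            make_classifier("lda"), X[:20], y[:20], X[20:], y[20:],
            all_classes=np.array(["A", "B", "C"]),
        )
        assert not np.any(scores.y_pred == "C")
        assert np.all(scores.proba[:, 2] == 0.0)

    def test_single_class_training_fold_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            train_and_score(make_classifier("lda"), X, np.zeros(4), X, np.zeros(4))

    @pytest.mark.parametrize("kind", ["rf", "lda", "knn", "svm"])
    def test_all_classifier_kinds_produce_normalized_scores(self, kind):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(i, 0.3, (8, 6)) for i in range(3)])
        y = np.repeat(list("ABC"), 8)
        scores = train_and_score(make_classifier(kind, random_state=0), X, y, X, y)
        np.testing.assert_allclose(scores.proba.sum(axis=1), 1.0, atol=1e-9)


class TestCrossValidation:
    def test_separable_subjects_reach_full_accuracy(self):
        data, _ = simulate_study(5, 3, 3, seed=8)
        assert cross_validated_accuracy(data, "limb", "lda") == 100.0

    def test_permuted_labels_fall_to_chance(self):
        data, _ = simulate_study(5, 4, 6, seed=9)
        rng = np.random.default_rng(0)
        data.meta["subject_id"] = rng.permutation(data.meta["subject_id"].to_numpy())
        acc = cross_validated_accuracy(data, "limb", "knn", seed=0)
        assert acc < 40.0  # chance = 20%


class TestRocOpenSet:
    def test_perfect_separation(self):
        r = roc_open_set((np.full(5, 0.9), np.full(7, 0.1)))
        assert r.eer == 0.0
        assert r.auc == 1.0

    def test_exchangeable_populations_approach_half(self):
        rng = np.random.default_rng(1)
        r = roc_open_set((rng.random(4000), rng.random(4000)))
        assert r.eer == pytest.approx(50.0, abs=2.0)
        assert r.auc == pytest.approx(0.5, abs=0.02)

    def test_worked_four_score_example_matches_oracle(self):
        genuine, impostor = [0.8, 0.6], [0.7, 0.2]
        r = roc_open_set((np.array(genuine), np.array(impostor)))
        eer, auc = brute_force_roc(genuine, impostor)
        assert r.eer == pytest.approx(eer, abs=1e-12)
        assert r.auc == pytest.approx(auc, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            roc_open_set((np.array([]), np.array([0.5])))


class TestConfusion:
    def _scores(self):
        classes = np.array(["A", "B"])
        y_true = np.array(["A", "A", "B", "B", "B"])
        proba = np.array([[0.9, 0.1], [0.2, 0.8], [0.3, 0.7], [0.6, 0.4], [0.1, 0.9]])
        y_pred = classes[proba.argmax(axis=1)]
        return ScoreSet(classes, y_true, y_pred, proba)

    def test_counts_and_trace_identity(self):
        scores = self._scores()
        mat = confusion(scores)
        assert mat.to_numpy().sum() == 5
        assert np.trace(mat.to_numpy()) / 5 * 100 == pytest.approx(scores.accuracy)
        # column sums = per-class prediction counts
        pred_counts = pd.Series(scores.y_pred).value_counts()
        for c in scores.classes:
            assert mat[c].sum() == pred_counts.get(c, 0)

    def test_all_correct_is_diagonal(self):
        classes = np.array(["A", "B"])
        proba = np.array([[1.0, 0.0], [0.0, 1.0]])
        scores = ScoreSet(classes, classes.copy(), classes.copy(), proba)
        mat = confusion(scores).to_numpy()
        assert np.all(mat == np.eye(2))


class TestScalability:
    def test_fit_recovers_exact_model(self):
        n = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        a_true, b_true, c_true = 91.5, 30.0, 1.2
        acc = a_true + b_true * n ** (-c_true)
        a_inf, b, c = fit_accuracy_asymptote(n, acc)
        assert a_inf == pytest.approx(a_true, abs=1e-6)
        assert c == pytest.approx(c_true, abs=1e-6)

    def test_full_cohort_is_deterministic_with_zero_sd(self):
        data, _ = simulate_study(6, 3, 3, seed=4)
        curve, fit = scalability_curve(
            data, subject_counts=[3, 4, 6], n_repeats=3, kind="knn",
            selection="limb", seed=0,
        )
        full = curve[curve.n_subjects == 6]
        assert full.n_repeats.iloc[0] == 1
        assert full.accuracy_sd.iloc[0] == 0.0
        assert np.isfinite(fit["a_inf"])

    def test_count_beyond_cohort_rejected(self):
        data, _ = simulate_study(4, 2, 2, seed=4)
        with pytest.raises(ValueError):
            scalability_curve(data, subject_counts=[5], kind="knn")
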