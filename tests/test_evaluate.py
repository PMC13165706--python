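"""Validation schemes, learners, and the performance metric equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score, f1_score, matthews_corrcoef

from honeynir.evaluate import (
    ConfusionMatrix,
    ModelSpec,
    bootstrap_eval,
    classification_metrics,
    confusion_from_labels,
    cross_validate,
    fit_predict,
    grid_search,
    pca_compress,
    regression_metrics,
    venetian_blind_folds,
)
from honeynir.preprocess import PreprocessSpec


def _counting_oracle(cm: ConfusionMatrix) -> dict:
    """Brute-force per-sample oracle for the four classification metrics."""
    samples = []
    c = len(cm.class_names)
    for i in range(c):
        for j in range(c):
            samples.extend([(i, j)] * int(cm.counts[i, j]))
    n = len(samples)
    acc = sum(t == p for t, p in samples) / n
    recalls, f1s = [], []
    for k in range(c):
        tp = sum(1 for t, p in samples if t == k and p == k)
        fn = sum(1 for t, p in samples if t == k and p != k)
        fp = sum(1 for t, p in samples if t != k and p == k)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    s = float(n)
    trace = sum(1 for t, p in samples if t == p)
    row = [sum(1 for t, _ in samples if t == k) for k in range(c)]
    col = [sum(1 for _, p in samples if p == k) for k in range(c)]
    denom = np.sqrt((s**2 - sum(x * x for x in col)) * (s**2 - sum(x * x for x in row)))
    mcc = 0.0 if denom == 0 else (trace * s - sum(r * q for r, q in zip(row, col))) / denom
    return {"accuracy": acc, "balanced_accuracy": float(np.mean(recalls)),
            "f1_macro": float(np.mean(f1s)), "mcc": float(mcc)}


class TestVenetianBlind:
    def test_definition(self):
        folds = venetian_blind_folds(10, 5)
        np.testing.assert_array_equal(folds.fold_of_row,
                                      [0, 1, 2, 3, 4, 0, 1, 2, 3, 4])

    def test_uneven_sizes(self):
        folds = venetian_blind_folds(7, 5)
        sizes = np.bincount(folds.fold_of_row, minlength=5)
        np.testing.assert_array_equal(sizes, [2, 2, 1, 1, 1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 10), st.integers(2, 200))
    def test_sizes_differ_by_at_most_one(self, k, extra):
        n = k + extra
        sizes = np.bincount(venetian_blind_folds(n, k).fold_of_row, minlength=k)
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            venetian_blind_folds(4, 5)


class TestPCACompress:
    def test_exact_rank_reconstruction(self, rng):
        base = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 20))
        T, _, components = pca_compress(base, None, 2)
        reconstructed = T @ components + base.mean(axis=0)
        np.testing.assert_allclose(reconstructed, base, atol=1e-8)

    def test_scores_uncorrelated_and_projection_consistent(self, rng):
        X = rng.normal(size=(15, 8))
        T_cal, T_val, _ = pca_compress(X, X, 4)
        corr = np.corrcoef(T_cal.T)
        np.testing.assert_allclose(corr - np.diag(np.diag(corr)), 0, atol=1e-8)
        np.testing.assert_allclose(T_cal, T_val, atol=1e-10)

    def test_range_check(self, rng):
        with pytest.raises(ValueError):
            pca_compress(rng.normal(size=(5, 8)), None, 7)


class TestFitPredict:
    def test_knn_one_neighbour_reproduces_training_labels(self, rng):
        X = rng.normal(size=(20, 6))
        y = np.array(["a", "b"] * 10, dtype=object)
        spec = ModelSpec("kNN", "classification", (("k", 1),), pca_components=4)
        np.testing.assert_array_equal(fit_predict(spec, X, y, X), y)

    def test_linear_svm_separates_linearly_separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(15, 4)) + 4, rng.normal(size=(15, 4)) - 4])
        y = np.array(["hi"] * 15 + ["lo"] * 15, dtype=object)
        spec = ModelSpec("SVM", "classification", (("kernel", "linear"),),
                         pca_components=2)
        np.testing.assert_array_equal(fit_predict(spec, X, y, X), y)

    def test_rf_seeded_reproducibility(self, rng):
        X = rng.normal(size=(30, 10))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        spec = ModelSpec("RF", "regression", (("n_trees", 200), ("max_depth", 10)),
                         pca_components=5)
        a = fit_predict(spec, X, y, X, seed=7)
        b = fit_predict(spec, X, y, X, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_model_spec_validation(self):
        with pytest.raises(ValueError, match="pca_components"):
            ModelSpec("RF", "regression", (("n_trees", 300),))
        with pytest.raises(ValueError, match="n_trees"):
            ModelSpec("RF", "regression", (("n_trees", 100),), pca_components=3)
        with pytest.raises(ValueError, match="PLS classification"):
            ModelSpec("PLS", "classification")
        with pytest.raises(ValueError, match="metric"):
            ModelSpec("kNN", "regression", (("metric", "cosine"),), pca_components=3)


class TestRegressionMetrics:
    def test_identity_and_constant(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, y)
        assert (m["r2"], m["rmse"], m["mae"]) == (1.0, 0.0, 0.0)
        m0 = regression_metrics(y, np.full(4, y.mean()))
        assert m0["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        m = regression_metrics([0, 1, 2, 3], [0, 1, 2, 7])
        assert m["rmse"] == pytest.approx(2.0)
        assert m["mae"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestClassificationMetrics:
    def test_perfect_three_class(self):
        cm = ConfusionMatrix(np.diag([4, 5, 6]), ("a", "b", "c"))
        m = classification_metrics(cm)
        assert m == {"accuracy": 1.0, "balanced_accuracy": 1.0,
                     "f1_macro": 1.0, "mcc": 1.0}

    def test_total_disagreement_two_class(self):
        cm = ConfusionMatrix(np.array([[0, 5], [5, 0]]), ("a", "b"))
        m = classification_metrics(cm)
        assert m["accuracy"] == 0.0
        assert m["mcc"] == pytest.approx(-1.0)

    def test_two_class_hand_example_matches_oracle(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ("a", "b"))
        m = classification_metrics(cm)
        oracle = _counting_oracle(cm)
        for key in m:
            assert m[key] == pytest.approx(oracle[key], abs=1e-12)

    def test_binary_mcc_equals_tp_tn_formula(self):
        tp, fn, fp, tn = 3, 1, 2, 4
        cm = ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ("pos", "neg"))
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert classification_metrics(cm)["mcc"] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_on_random_labels(self, rng):
        for _ in range(20):
            c = int(rng.integers(2, 5))
            names = [str(i) for i in range(c)]
            y_true = rng.integers(0, c, size=60).astype(str)
            y_pred = rng.integers(0, c, size=60).astype(str)
            if len(set(y_true)) < c:
                continue
            m = classification_metrics(confusion_from_labels(y_true, y_pred, names))
            assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)
            assert m["balanced_accuracy"] == pytest.approx(
                balanced_accuracy_score(y_true, y_pred), abs=1e-10)
            assert m["f1_macro"] == pytest.approx(
                f1_score(y_true, y_pred, labels=names, average="macro",
                         zero_division=0.0), abs=1e-10)

    def test_balanced_classes_make_ba_equal_accuracy(self):
        cm = ConfusionMatrix(np.array([[7, 3], [2, 8]]), ("a", "b"))
        m = classification_metrics(cm)
        assert m["balanced_accuracy"] == pytest.approx(m["accuracy"])

    def test_imbalance_lets_accuracy_exceed_ba(self):
        # majority class dominates: high accuracy, chance-level BA
        cm = ConfusionMatrix(np.array([[70, 0, 0], [9, 1, 0], [18, 0, 2]]),
                             ("a", "b", "c"))
        m = classification_metrics(cm)
        assert m["accuracy"] > 0.7
        assert m["balanced_accuracy"] < 0.5
        assert m["accuracy"] > m["balanced_accuracy"] + 0.2


class TestBootstrapAndCV:
    def _xy(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = X[:, 0] * 2 + 0.3 * rng.normal(size=n)
        return X, y

    def test_bootstrap_reproducible_and_perfect_classifier(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(20, 4)) + 6, rng.normal(size=(20, 4)) - 6])
        y = np.array(["hi"] * 20 + ["lo"] * 20, dtype=object)
        spec = ModelSpec("SVM", "classification", (("kernel", "linear"),),
                         pca_components=2)
        res1 = bootstrap_eval(spec, PreprocessSpec(), X, y, B=20, seed=5)
        res2 = bootstrap_eval(spec, PreprocessSpec(), X, y, B=20, seed=5)
        assert res1.metrics == res2.metrics
        assert res1.metrics["balanced_accuracy"] == 1.0

    def test_bootstrap_mean_stabilises_with_iterations(self):
        X, y = self._xy(seed=2, n=50)
        spec = ModelSpec("PLS", "regression", (("n_lv", 3),))
        small = bootstrap_eval(spec, PreprocessSpec(), X, y, B=100, seed=0)
        large = bootstrap_eval(spec, PreprocessSpec(), X, y, B=400, seed=1)
        se = small.extras["metric_sd"]["r2"] / np.sqrt(small.extras["n_scored"])
        assert abs(small.metrics["r2"] - large.metrics["r2"]) < 4 * se

    def test_cross_validate_refits_preprocessing_per_fold(self):
        # adversarial set: one fold carries a huge offset; leaking its
        # statistics into the fit changes the scaling and the metrics
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 8))
        X[::5] += 50.0
        y = X[:, 0] + rng.normal(size=25)
        spec = ModelSpec("PLS", "regression", (("n_lv", 2),))
        preproc = PreprocessSpec(scaling="autoscale")
        folds = venetian_blind_folds(25, 5)
        honest = cross_validate(spec, preproc, X, y, folds)
        from honeynir.preprocess import fit_apply

        Xleak, _, _ = fit_apply(preproc, X)  # fitted on everything: leaky
        leaky = cross_validate(spec, PreprocessSpec(), Xleak, y, folds)
        assert honest.metrics["rmse"] != pytest.approx(leaky.metrics["rmse"],
                                                       rel=1e-6)


class TestGridSearch:
    def test_single_candidate_and_monotonicity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        good = ModelSpec("PLS", "regression", (("n_lv", 3),))
        bad = ModelSpec("PLS", "regression", (("n_lv", 1),))
        pre = [PreprocessSpec()]
        best_single, board = grid_search("regression", pre, [good], X, y)
        assert best_single.model == good and len(board) == 1
        best_both, board2 = grid_search("regression", pre, [good, bad], X, y)
        assert best_both.model == good
        assert best_both.metrics["rmse"] == min(r.metrics["rmse"] for r in board2)

    def test_tie_break_prefers_simpler_model(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = X @ np.array([1.0, 1, 1, 1])  # noiseless: several models tie at ~0
        models = [ModelSpec("PLS", "regression", (("n_lv", a),)) for a in (4, 2)]
        best, _ = grid_search("regression", [PreprocessSpec()], models, X, y)
        # both reach machine-precision RMSE but not bitwise ties; just check
        # the winner is on the leaderboard minimum
        assert best.metrics["rmse"] <= 1e-8
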