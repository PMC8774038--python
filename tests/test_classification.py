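import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mi_erd import (
    ClassifierSpec,
    compute_metrics,
    cross_validated_predictions,
    tune_hyperparameters,
)
from mi_erd.classification import _cv_loss, make_estimator
from mi_erd.data_io import InputError


def brute_force_auc(y_true, scores, positive_label):
    """All-pairs oracle: P(score_pos > score_neg), ties counted half."""
    pos = [s for yt, s in zip(y_true, scores) if yt == positive_label]
    neg = [s for yt, s in zip(y_true, scores) if yt != positive_label]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2))
    X = np.column_stack([
        np.where(y == "a", -2.0, 2.0) + 0.1 * rng.normal(size=n),
        rng.normal(size=n),
    ])
    return X, y


class TestComputeMetrics:
    def test_confusion_count_worked_example(self):
        # 194 true positives, 6 false negatives, 199 true negatives, 1 false positive
        y_true = np.array(["pos"] * 200 + ["neg"] * 200)
        y_pred = np.array(["pos"] * 194 + ["neg"] * 6 + ["neg"] * 199 + ["pos"])
        rep = compute_metrics(y_true, y_pred, positive_label="pos")
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (194, 199, 1, 6)
        assert rep.sensitivity == pytest.approx(0.97)
        assert rep.specificity == pytest.approx(0.995)
        assert rep.accuracy == pytest.approx(0.9825)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(derandomize=True, max_examples=200)
    def test_ratio_identities_for_any_counts(self, tp, tn, fp, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        y_true = np.array(["p"] * (tp + fn) + ["n"] * (tn + fp))
        y_pred = np.array(["p"] * tp + ["n"] * fn + ["n"] * tn + ["p"] * fp)
        rep = compute_metrics(y_true, y_pred, positive_label="p")
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert 0 <= rep.auc <= 1

    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "b"])
        scores = np.array([0.0, 1.0, 0.1, 0.9])
        rep = compute_metrics(y, y, scores, positive_label="b")
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_tied_scores_give_half_auc(self):
        y = np.array(["a", "b"] * 10)
        rep = compute_metrics(y, y, np.zeros(20), positive_label="b")
        assert rep.auc == pytest.approx(0.5)

    def test_auc_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        y = rng.choice(["a", "b"], size=150)
        if len(set(y)) < 2:  # pragma: no cover - guard for tiny draw
            y[0], y[1] = "a", "b"
        scores = np.round(rng.normal(size=150), 1)  # rounding forces ties
        rep = compute_metrics(y, y, scores, positive_label="b")
        assert rep.auc == pytest.approx(brute_force_auc(y, scores, "b"), abs=1e-12)

    def test_swapping_positive_label_swaps_sens_spec(self):
        rng = np.random.default_rng(12)
        y_true = rng.choice(["a", "b"], size=80)
        y_pred = rng.choice(["a", "b"], size=80)
        ra = compute_metrics(y_true, y_pred, positive_label="a")
        rb = compute_metrics(y_true, y_pred, positive_label="b")
        assert ra.sensitivity == pytest.approx(rb.specificity)
        assert ra.specificity == pytest.approx(rb.sensitivity)
        assert ra.accuracy == pytest.approx(rb.accuracy)

    def test_unknown_positive_label_raises(self):
        with pytest.raises(InputError):
            compute_metrics(np.array(["a", "b"]), np.array(["a", "b"]),
                            positive_label="z")

    def test_rounded_percentage_output(self):
        y_true = np.array(["p"] * 200 + ["n"] * 200)
        y_pred = np.array(["p"] * 194 + ["n"] * 6 + ["n"] * 199 + ["p"])
        style = compute_metrics(y_true, y_pred, positive_label="p").rounded_percent()
        assert style["sensitivity"] == "97%"


class TestTuning:
    def test_separable_data_reaches_zero_loss(self):
        X, y = _separable_data()
        for strategy in ("random", "bayesian"):
            spec = ClassifierSpec(kind="SVM", tuning_budget=15,
                                  tuning_strategy=strategy, seed=0)
            _, loss = tune_hyperparameters(X, y, spec)
            assert loss == 0.0

    def test_deterministic_given_seed(self, small_planted):
        X, y, _ = small_planted
        spec = ClassifierSpec(kind="TREE", tuning_budget=10, seed=5)
        p1, l1 = tune_hyperparameters(X, y, spec)
        p2, l2 = tune_hyperparameters(X, y, spec)
        assert p1 == p2 and l1 == l2

    def test_knn_matches_exhaustive_grid(self):
        rng = np.random.default_rng(20)
        y = np.array(["a", "b"] * 20)
        X = np.column_stack([np.where(y == "a", 0.0, 1.0) + 0.6 * rng.normal(size=40),
                             rng.normal(size=40)])
        spec = ClassifierSpec(kind="KNN", tuning_budget=60,
                              tuning_strategy="random", seed=0,
                              search_space={"n_neighbors": ("int", 1, 30),
                                            "metric": ("cat", ("euclidean",))})
        params, loss = tune_hyperparameters(X, y, spec)
        grid = {k: _cv_loss(X, y, "KNN",
                            {"n_neighbors": k, "metric": "euclidean"}, 5, 0)
                for k in range(1, 31)}
        assert loss == pytest.approx(min(grid.values()))
        assert grid[params["n_neighbors"]] == pytest.approx(min(grid.values()))

    def test_tuned_never_worse_than_defaults(self, small_planted):
        X, y, _ = small_planted
        for kind in ("SVM", "KNN", "TREE"):
            spec = ClassifierSpec(kind=kind, tuning_budget=15, seed=2)
            _, tuned_loss = tune_hyperparameters(X, y, spec)
            from mi_erd.classification import DEFAULT_PARAMS
            default_loss = _cv_loss(X, y, kind, DEFAULT_PARAMS[kind], 5, spec.seed)
            assert tuned_loss <= default_loss + 1e-12

    def test_degenerate_features_warn_and_default(self):
        X = np.ones((20, 3))
        y = np.array(["a", "b"] * 10)
        spec = ClassifierSpec(kind="SVM", tuning_budget=5, seed=0)
        with pytest.warns(UserWarning):
            params, _ = tune_hyperparameters(X, y, spec)
        assert params == {"kernel": "rbf", "C": 1.0, "gamma": "scale"}


class TestCrossValidatedPredictions:
    def test_every_trial_predicted_once(self):
        X, y = _separable_data(n=100, seed=1)
        spec = ClassifierSpec(kind="KNN", tune=False)
        y_pred, scores = cross_validated_predictions(X, y, spec, folds=5, seed=0)
        assert len(y_pred) == len(scores) == 100
        assert set(y_pred) <= {"a", "b"}

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(200, 10))
        y = np.array(["a", "b"] * 100)  # labels independent of X
        spec = ClassifierSpec(kind="SVM", tune=False)
        y_pred, _ = cross_validated_predictions(X, y, spec, folds=5, seed=0)
        acc = np.mean(y_pred == y)
        assert 0.35 <= acc <= 0.65

    def test_planted_features_reach_high_accuracy(self, small_planted):
        X, y, _ = small_planted
        spec = ClassifierSpec(kind="SVM", tuning_budget=15,
                              tuning_strategy="random", seed=0)
        y_pred, scores = cross_validated_predictions(X, y, spec, folds=5, seed=0)
        rep = compute_metrics(y, y_pred, scores)
        assert rep.accuracy >= 0.9
        assert rep.auc >= 0.9

    def test_small_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(InputError):
            cross_validated_predictions(X, y, ClassifierSpec(kind="KNN", tune=False),
                                        folds=5, seed=0)

    def test_scores_orient_toward_larger_label(self):
        X, y = _separable_data(n=60, seed=3)
        spec = ClassifierSpec(kind="SVM", tune=False)
        y_pred, scores = cross_validated_predictions(X, y, spec, folds=5, seed=0)
        assert scores[y == "b"].mean() > scores[y == "a"].mean()


class TestEstimators:
    @pytest.mark.parametrize("kind", ["SVM", "KNN", "TREE"])
    def test_fit_predict_roundtrip(self, kind):
        X, y = _separable_data()
        est = make_estimator(kind)
        est.fit(X, y)
        assert np.mean(est.predict(X) == y) > 0.9
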