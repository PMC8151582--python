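"""Base classifiers, ensemble vote, metrics, comparison and variability."""

import numpy as np
import pandas as pd
import pytest

from ehgkit.models import (
    ClassifierSpec,
    compare_classifiers,
    compute_metrics,
    fit_predict,
    majority_vote,
    variability_report,
)
from oracles import friedman_bruteforce


def separable_toy(rng, n=40):
    X = np.vstack([rng.normal(-3, 0.3, (n // 2, 2)), rng.normal(3, 0.3, (n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestClassifierSpec:
    def test_even_knn_k_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("knn", knn_k=4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm")


class TestFitPredict:
    @pytest.mark.parametrize("kind", ["knn", "lda", "lr"])
    def test_separable_training_accuracy(self, rng, kind):
        X, y = separable_toy(rng)
        labels, scores = fit_predict(ClassifierSpec(kind), X, y, X)
        assert np.array_equal(labels, y)
        assert scores.min() >= 0 and scores.max() <= 1

    def test_knn_vote_fraction(self):
        # 3 preterm / 2 term among the 5 nearest neighbours -> score 0.6
        X_train = np.array([[0.0], [0.1], [0.2], [0.3], [0.4], [10.0], [11.0]])
        y_train = np.array([1, 1, 1, 0, 0, 0, 0])
        labels, scores = fit_predict(
            ClassifierSpec("knn", standardize=False), X_train, y_train, [[0.15]]
        )
        assert labels[0] == 1
        assert scores[0] == pytest.approx(0.6)

    @pytest.mark.parametrize("kind", ["lda", "lr"])
    def test_training_order_invariance(self, rng, kind):
        X, y = separable_toy(rng)
        X_eval = rng.normal(0, 3, (20, 2))
        perm = rng.permutation(len(y))
        l1, s1 = fit_predict(ClassifierSpec(kind), X, y, X_eval)
        l2, s2 = fit_predict(ClassifierSpec(kind), X[perm], y[perm], X_eval)
        assert np.array_equal(l1, l2)
        assert np.allclose(s1, s2, atol=1e-6)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [((1, 1, 0), 1), ((0, 0, 0), 0), ((1, 1, 1), 1), ((0, 1, 0), 0)],
    )
    def test_truth_table(self, votes, expected):
        out = majority_vote([votes[0]], [votes[1]], [votes[2]])
        assert out[0] == expected

    def test_tiebreaker_is_majority_pair(self, rng):
        # wherever two classifiers disagree, the third decides
        a = rng.integers(0, 2, 100)
        b = 1 - a
        c = rng.integers(0, 2, 100)
        assert np.array_equal(majority_vote(a, b, c), c)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            majority_vote([1, 0], [1], [0, 1])


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array([1] * 45 + [0] * 5 + [1] * 5 + [0] * 45)
        scores = y_pred + 0.0
        m = compute_metrics(y_true, y_pred, scores)
        for key in ("accuracy", "f1", "sensitivity", "specificity", "ppv", "npv"):
            assert m[key] == pytest.approx(0.9)

    def test_perfect_separation_auc(self, rng):
        y = rng.integers(0, 2, 200)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 200)
        scores = y + rng.uniform(-0.4, 0.4, 200)
        m = compute_metrics(y, (scores >= 0.5).astype(int), scores)
        assert m["auc"] == 1.0

    def test_random_scores_auc_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        scores = rng.uniform(0, 1, 2000)
        m = compute_metrics(y, (scores >= 0.5).astype(int), scores)
        assert m["auc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])


class TestCompareClassifiers:
    def test_identical_columns_no_significance(self, rng):
        col = rng.uniform(0.7, 0.9, 30)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        res = compare_classifiers(df)
        assert res.friedman_p == 1.0
        assert not res.significant.to_numpy().any()

    def test_dominant_classifier_flagged_against_both(self, rng):
        base = rng.uniform(0.6, 0.8, 30)
        df = pd.DataFrame({"a": base + 0.15, "b": base, "c": base})
        res = compare_classifiers(df)
        assert res.significant.loc["a", "b"] and res.significant.loc["a", "c"]
        assert not res.significant.loc["b", "c"]
        assert res.significant.equals(res.significant.T)

    def test_friedman_statistic_matches_textbook_formula(self, rng):
        for _ in range(50):
            data = rng.standard_normal((8, 4))
            res = compare_classifiers(pd.DataFrame(data, columns=list("abcd")))
            assert res.friedman_statistic == pytest.approx(
                friedman_bruteforce(data), rel=1e-12
            )

    def test_hand_rankable_table(self):
        # per-row ranks: col c always 3, col b always 2, col a always 1
        data = np.array([[0.1, 0.2, 0.3]] * 5) + np.arange(5)[:, None]
        res = compare_classifiers(pd.DataFrame(data, columns=list("abc")), alpha=0.05)
        # mean ranks (1, 2, 3): chi2 = 12*5/(3*4) * (1 + 4 + 9) - 3*5*4 = 10
        assert res.friedman_statistic == pytest.approx(10.0)


class TestVariabilityReport:
    def _frame(self, values_by_clf):
        rows = []
        for clf, vals in values_by_clf.items():
            for i, v in enumerate(vals):
                rows.append({"classifier": clf, "partition": i, "f1": v})
        return pd.DataFrame(rows)

    def test_constant_metric_zero_cv(self):
        rep = variability_report(self._frame({"lda": [0.9, 0.9, 0.9]}))
        assert rep.loc["lda", "f1"] == 0.0

    def test_two_point_cv_value(self):
        rep = variability_report(self._frame({"lda": [0.8, 1.0]}))
        assert rep.loc["lda", "f1"] == pytest.approx(np.sqrt(0.02) / 0.9)

    def test_scale_invariance(self):
        vals = [0.41, 0.52, 0.38, 0.6]
        a = variability_report(self._frame({"x": vals})).loc["x", "f1"]
        b = variability_report(self._frame({"x": [2 * v for v in vals]})).loc["x", "f1"]
        assert a == pytest.approx(b)

    def test_base_summary_rows(self):
        rep = variability_report(
            self._frame({"knn": [0.7, 0.9], "lda": [0.8, 0.82],
                         "ensemble": [0.85, 0.86]})
        )
        assert {"base_min", "base_mean", "base_max"} <= set(rep.index)
        assert rep.loc["base_min", "f1"] <= rep.loc["base_max", "f1"]
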