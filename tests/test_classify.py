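import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from gistate.classify import (
    GastricStateClassifier,
    _grid,
    accuracy_ci,
    chance_level,
    evaluate,
    exhaustive_feature_selection,
    greedy_feature_selection,
    grid_search_cv,
    metrics_from_confusion,
    split_train_test,
)
from gistate.config import PipelineConfig


def separable_table(n_per_class=20, n_noise=4, seed=0, classes=("a", "b", "c")):
    """Balanced table: feature f0 separates the classes, the rest are noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, label in enumerate(classes):
        for _ in range(n_per_class):
            rows.append(
                {
                    "source_id": "paddle:A",
                    "label": label,
                    "f0": ci * 10.0 + rng.normal(0, 0.5),
                    **{f"f{j}": rng.normal(0, 1) for j in range(1, n_noise + 1)},
                }
            )
    return pd.DataFrame(rows)


FEATS = ["f0", "f1", "f2", "f3", "f4"]


class TestSplit:
    def test_stratified_counts(self):
        table = separable_table(n_per_class=20)
        train, test = split_train_test(table, 0.2, seed=0)
        assert len(test) == 12
        assert test["label"].value_counts().tolist() == [4, 4, 4]

    def test_same_seed_same_split(self):
        table = separable_table()
        a = split_train_test(table, 0.2, seed=5)[1]
        b = split_train_test(table, 0.2, seed=5)[1]
        pd.testing.assert_frame_equal(a, b)

    def test_partition(self):
        table = separable_table().reset_index().rename(columns={"index": "rid"})
        train, test = split_train_test(table, 0.2, seed=1)
        assert set(train.rid) & set(test.rid) == set()
        assert set(train.rid) | set(test.rid) == set(table.rid)


class TestGridSearch:
    def test_grid_sizes(self):
        cfg = PipelineConfig()
        assert len(_grid("knn", cfg)) == 10
        assert len(_grid("svm_rbf", cfg)) == 8

    def test_separable_data_reach_perfect_cv(self):
        table = separable_table()
        X = table[FEATS].to_numpy()
        y = table["label"].to_numpy()
        for algo in ("knn", "svm_rbf"):
            params, acc = grid_search_cv(X, y, algo, seed=0)
            if algo == "knn":
                assert acc == 1.0
            else:
                assert acc > 0.9  # tiny-gamma RBF needs the wide-C end

    def test_tie_break_prefers_smaller_model(self):
        # perfectly separable: many k tie at accuracy 1 -> smallest k wins
        table = separable_table()
        params, acc = grid_search_cv(
            table[FEATS].to_numpy(), table["label"].to_numpy(), "knn", seed=0
        )
        assert params == {"n_neighbors": 1}

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            grid_search_cv(X, np.zeros(10), "knn")


class TestGreedySelection:
    def test_matches_exhaustive_on_single_informative_feature(self):
        table = separable_table(n_per_class=10, seed=3)
        X = table[FEATS].to_numpy()
        y = table["label"].to_numpy()
        greedy = greedy_feature_selection(X, y, "knn", seed=0)
        exhaustive = exhaustive_feature_selection(X, y, "knn", seed=0)
        assert greedy["selected"] == [0]
        assert exhaustive["selected"] == [0]
        assert greedy["cv_accuracy"] == exhaustive["cv_accuracy"] == 1.0

    def test_duplicate_features_pick_one(self, rng):
        table = separable_table(n_per_class=10, seed=4)
        X = np.repeat(table[["f0"]].to_numpy(), 4, axis=1)  # 4 identical copies
        sel = greedy_feature_selection(X, table["label"].to_numpy(), "knn", seed=0)
        assert len(sel["selected"]) == 1

    def test_trace_non_decreasing(self):
        table = separable_table(n_per_class=8, seed=5)
        noisy = table.copy()
        noisy["f0"] += np.random.default_rng(0).normal(0, 6, len(noisy))
        sel = greedy_feature_selection(
            noisy[FEATS].to_numpy(), noisy["label"].to_numpy(), "knn", seed=0
        )
        trace = sel["trace"]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_top_subsets_sorted_and_capped(self):
        table = separable_table(n_per_class=8, seed=6)
        sel = greedy_feature_selection(
            table[FEATS].to_numpy(), table["label"].to_numpy(), "knn", seed=0
        )
        accs = [s["cv_accuracy"] for s in sel["top_subsets"]]
        assert accs == sorted(accs, reverse=True)
        assert len(sel["top_subsets"]) <= 10


class TestEstimatorContract:
    def test_fit_predict_and_params(self):
        table = separable_table()
        clf = GastricStateClassifier(algorithm="knn", random_state=0)
        assert clone(clf).get_params()["algorithm"] == "knn"
        X = table[FEATS].to_numpy()
        y = table["label"].to_numpy()
        clf.fit(X, y)
        assert clf.selected_features_ == [0]
        assert list(clf.classes_) == ["a", "b", "c"]
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_knn1_resubstitution_is_perfect(self, rng):
        # wiring sanity: a 1-NN model recalls its own training points
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30).astype(str)
        clf = GastricStateClassifier(
            algorithm="knn", feature_selection=False, random_state=0
        )
        clf.fit(X, y)
        clf.estimator_.set_params(n_neighbors=1)
        clf.estimator_.fit(X[:, clf.selected_features_], y)
        assert np.mean(clf.predict(X) == y) == 1.0


class TestEvaluate:
    def test_perfect_predictions(self):
        table = separable_table(n_per_class=8)
        clf = GastricStateClassifier("knn", feature_selection=False, random_state=0)
        X = table[FEATS].to_numpy()
        y = table["label"].to_numpy()
        clf.fit(X, y)
        res = evaluate(clf, X, y)
        assert res["accuracy"] == 1.0
        assert all(m["precision"] == 1.0 for m in res["per_class"].values())

    def test_hand_confusion_matrix(self):
        # 2-class: TP=4, TN=4, FP=1, FN=1 for each class by symmetry
        res = metrics_from_confusion(np.array([[4, 1], [1, 4]]), ["pos", "neg"])
        assert res["accuracy"] == pytest.approx(0.8)
        for m in res["per_class"].values():
            assert m["sensitivity"] == pytest.approx(0.8)
            assert m["specificity"] == pytest.approx(0.8)
            assert m["precision"] == pytest.approx(0.8)

    def test_metrics_consistent_with_stored_matrix(self, rng):
        cm = rng.integers(0, 10, (3, 3))
        res = metrics_from_confusion(cm, ["a", "b", "c"])
        cm = np.asarray(res["confusion_matrix"])
        assert res["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())
        for i, cls in enumerate(res["classes"]):
            tp = cm[i, i]
            assert res["per_class"][cls]["sensitivity"] == pytest.approx(
                tp / cm[i].sum()
            )

    def test_absent_class_gives_nan_sensitivity(self):
        res = metrics_from_confusion(np.array([[0, 0], [1, 5]]), ["a", "b"])
        assert np.isnan(res["per_class"]["a"]["sensitivity"])


class TestChanceLevel:
    def test_three_class_chance_near_third(self):
        table = separable_table(n_per_class=10, seed=7)
        ch = chance_level(table, "knn", n_scrambles=40, seed=9, feature_cols=FEATS)
        assert ch["mean"] == pytest.approx(1 / 3, abs=0.08)

    def test_two_class_chance_near_half(self):
        table = separable_table(n_per_class=12, seed=8, classes=("early", "late"))
        ch = chance_level(table, "knn", n_scrambles=40, seed=10, feature_cols=FEATS)
        assert ch["mean"] == pytest.approx(0.5, abs=0.08)

    def test_chance_invariant_to_feature_scaling(self):
        table = separable_table(n_per_class=10, seed=11)
        scaled = table.copy()
        scaled[FEATS] = scaled[FEATS] * 1000.0
        a = chance_level(table, "knn", n_scrambles=25, seed=2, feature_cols=FEATS)
        b = chance_level(scaled, "knn", n_scrambles=25, seed=2, feature_cols=FEATS)
        assert a["mean"] == pytest.approx(b["mean"], abs=1e-12)

    def test_too_few_scrambles_rejected(self):
        with pytest.raises(ValueError):
            chance_level(separable_table(), n_scrambles=5, feature_cols=FEATS)


class TestAccuracyCI:
    def test_separable_data_ci_near_zero(self):
        table = separable_table(n_per_class=15, seed=12)
        res = accuracy_ci(
            table, "knn", repeats=8, seed=0, feature_cols=FEATS,
            feature_selection=False,
        )
        assert res["mean_accuracy"] == 1.0
        assert res["ci95"] == 0.0
        assert len(res["seeds"]) == 8

    def test_pooled_matrix_consistent_with_mean_accuracy(self):
        table = separable_table(n_per_class=10, seed=13)
        noisy = table.copy()
        noisy["f0"] += np.random.default_rng(1).normal(0, 8, len(noisy))
        res = accuracy_ci(
            noisy, "knn", repeats=6, seed=1, feature_cols=FEATS,
            feature_selection=False,
        )
        cm = np.asarray(res["pooled"]["confusion_matrix"])
        assert np.trace(cm) / cm.sum() == pytest.approx(res["mean_accuracy"])
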