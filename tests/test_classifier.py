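import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

from varforest.classifier import (DEFAULT_ALGORITHMS, ForestVariantClassifier,
                                  TrainingSet, build_training_set,
                                  compare_algorithms, f1_from_counts,
                                  load_model, merge_final_sets, save_model,
                                  train)
from varforest.features import FEATURE_NAMES
from varforest.filters import QcLabel


def synthetic_features(n_high, n_low, seed, separation=1.0):
    """Two-class feature frame; separation 0 = identical distributions."""
    rng = np.random.default_rng(seed)
    n = n_high + n_low
    X = pd.DataFrame(rng.normal(size=(n, 7)), columns=FEATURE_NAMES)
    y = np.array([1] * n_high + [0] * n_low)
    X.loc[y == 1, "mean_gq"] += 90 * separation
    X.loc[y == 1, "mean_dp"] += 30 * separation
    X.loc[y == 0, "outlier_gq"] += 2 * separation
    return X, y


class TestBuildTrainingSet:
    def test_downsamples_majority_high(self):
        X, y = synthetic_features(1000, 100, seed=0)
        labels = np.where(y == 1, "HIGH", "LOW")
        ts = build_training_set(X, labels, seed=3)
        assert len(ts.y) == 200
        assert ts.y.sum() == 100  # balanced: twice the minority count

    def test_no_sampling_when_balanced(self):
        X, y = synthetic_features(100, 100, seed=0)
        ts = build_training_set(X, np.where(y == 1, "HIGH", "LOW"), seed=3)
        assert len(ts.y) == 200

    def test_downsamples_majority_low_symmetrically(self):
        X, y = synthetic_features(50, 400, seed=0)
        ts = build_training_set(X, np.where(y == 1, "HIGH", "LOW"), seed=3)
        assert len(ts.y) == 100 and ts.y.sum() == 50

    def test_deterministic_given_seed(self):
        X, y = synthetic_features(500, 60, seed=0)
        labels = np.where(y == 1, "HIGH", "LOW")
        a = build_training_set(X, labels, seed=9)
        b = build_training_set(X, labels, seed=9)
        assert np.array_equal(a.ids, b.ids)

    def test_empty_class_fatal(self):
        X, _ = synthetic_features(10, 0, seed=0)
        with pytest.raises(ValueError, match="empty class"):
            build_training_set(X, np.array(["HIGH"] * 10), seed=0)

    def test_accepts_qclabel_values(self):
        X, y = synthetic_features(5, 5, seed=0)
        labels = [QcLabel.HIGH if v else QcLabel.LOW for v in y]
        ts = build_training_set(X, labels, seed=0)
        assert len(ts.y) == 10


class TestForestVariantClassifier:
    def test_sklearn_protocol(self):
        clf = ForestVariantClassifier(n_trees=10, random_state=1)
        params = clf.get_params()
        assert params["n_trees"] == 10
        clone(clf)  # must be clonable
        clf.set_params(probability_threshold=0.7)
        assert clf.probability_threshold == 0.7

    def test_separable_classes_near_perfect_f1(self):
        X, y = synthetic_features(400, 400, seed=1)
        Xtr, Xte, ytr, yte = train_test_split(X, y, random_state=0, stratify=y)
        clf = ForestVariantClassifier(random_state=0).fit(Xtr, ytr)
        assert f1_score(yte, clf.predict(Xte)) >= 0.99

    def test_permuted_labels_near_chance(self):
        X, y = synthetic_features(400, 400, seed=2, separation=0.0)
        rng = np.random.default_rng(5)
        y = rng.permutation(y)
        Xtr, Xte, ytr, yte = train_test_split(X, y, random_state=0, stratify=y)
        clf = ForestVariantClassifier(random_state=0).fit(Xtr, ytr)
        assert abs(f1_score(yte, clf.predict(Xte)) - 0.5) <= 0.1

    def test_ensemble_beats_single_tree_on_noisy_data(self):
        wins = 0
        for seed in range(10):
            X, y = synthetic_features(300, 300, seed=seed, separation=0.02)
            Xtr, Xte, ytr, yte = train_test_split(X, y, random_state=seed,
                                                  stratify=y)
            f1s = {}
            for k in (1, 50):
                clf = ForestVariantClassifier(n_trees=k, random_state=seed).fit(Xtr, ytr)
                f1s[k] = f1_score(yte, clf.predict(Xte))
            wins += f1s[50] >= f1s[1]
        assert wins >= 9

    def test_strict_threshold_at_half(self):
        clf = ForestVariantClassifier(n_trees=2, probability_threshold=0.5,
                                      random_state=0)
        X, y = synthetic_features(20, 20, seed=3)
        clf.fit(X, y)
        # with 2 trees probabilities are in {0, .5, 1}: exactly 0.5 -> LOW
        p = clf.probability_high(X)
        pred = clf.predict(X)
        assert np.array_equal(pred, (p > 0.5).astype(int))
        if (p == 0.5).any():
            assert (pred[p == 0.5] == 0).all()

    def test_threshold_monotonicity(self):
        X, y = synthetic_features(200, 200, seed=4, separation=0.1)
        clf = ForestVariantClassifier(random_state=0).fit(X, y)
        counts = []
        for t in np.arange(0.1, 1.0, 0.1):
            clf.probability_threshold = t
            counts.append(int(clf.predict(X).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_feature_order_mismatch_fatal(self):
        X, y = synthetic_features(20, 20, seed=5)
        clf = ForestVariantClassifier(n_trees=5, random_state=0).fit(X, y)
        shuffled = X[list(reversed(X.columns))]
        with pytest.raises(ValueError, match="feature order"):
            clf.predict(shuffled)

    def test_na_features_median_imputed_and_flagged(self):
        X, y = synthetic_features(50, 50, seed=6)
        clf = ForestVariantClassifier(n_trees=5, random_state=0).fit(X, y)
        Xna = X.head(3).copy()
        Xna.iloc[0, 0] = np.nan
        assert clf.imputed_mask(Xna).tolist() == [True, False, False]
        assert len(clf.predict(Xna)) == 3  # every variant still labelled

    def test_constant_features_warn(self):
        X, y = synthetic_features(20, 20, seed=7)
        X["gc"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            ForestVariantClassifier(n_trees=2, random_state=0).fit(X, y)


class TestFeatureImportance:
    def test_importances_normalised(self):
        X, y = synthetic_features(100, 100, seed=8)
        clf = ForestVariantClassifier(random_state=0).fit(X, y)
        assert clf.feature_importances_.sum() == pytest.approx(1.0, abs=1e-9)
        assert (clf.feature_importances_ >= 0).all()

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(600, 7)), columns=FEATURE_NAMES)
        y = np.array([1] * 300 + [0] * 300)
        X.loc[y == 1, "mean_gq"] += 5  # only informative feature
        clf = ForestVariantClassifier(random_state=0).fit(X, y)
        imp = dict(zip(clf.feature_order_, clf.feature_importances_))
        assert max(imp, key=imp.get) == "mean_gq"

    def test_exchangeable_noise_near_uniform(self):
        devs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(400, 7)), columns=FEATURE_NAMES)
            y = rng.integers(0, 2, size=400)
            clf = ForestVariantClassifier(random_state=seed).fit(X, y)
            devs.append(np.abs(clf.feature_importances_ - 1 / 7).max())
        assert max(devs) <= 0.1


class TestSerialization:
    def test_roundtrip_identical_predictions(self, tmp_path):
        X, y = synthetic_features(100, 100, seed=10)
        clf = ForestVariantClassifier(random_state=0).fit(X, y)
        save_model(clf, tmp_path / "m.joblib")
        loaded = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(clf.probability_high(X),
                                      loaded.probability_high(X))

    def test_feature_order_checked_on_load(self, tmp_path):
        X, y = synthetic_features(30, 30, seed=11)
        clf = ForestVariantClassifier(n_trees=3, random_state=0).fit(X, y)
        save_model(clf, tmp_path / "m.joblib")
        with pytest.raises(ValueError, match="feature order"):
            load_model(tmp_path / "m.joblib",
                       expected_feature_order=list(reversed(FEATURE_NAMES)))


class TestMergeFinalSets:
    def test_arithmetic(self):
        pred = {i: (QcLabel.HIGH if i < 82 else QcLabel.LOW) for i in range(70, 90)}
        high, low = merge_final_sets(set(range(70)), set(range(90, 100)), pred)
        assert len(high) == 82 and len(low) == 18
        assert high | low == set(range(100)) and not (high & low)

    def test_zero_undetermined(self):
        high, low = merge_final_sets({1, 2}, {3}, {})
        assert high == {1, 2} and low == {3}

    def test_overlap_fatal(self):
        with pytest.raises(ValueError, match="overlap"):
            merge_final_sets({1}, {1}, {})


class TestCompareAlgorithms:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (10, 0, 0, 1.0),
        (10, 10, 0, 2 / 3),
        (90, 10, 10, 0.9),
    ])
    def test_f1_formula(self, tp, fp, fn, expected):
        assert f1_from_counts(tp, fp, fn) == pytest.approx(expected)

    def test_table_sorted_by_f1(self):
        X, y = synthetic_features(120, 120, seed=12, separation=0.2)
        table = compare_algorithms(X, y, folds=4, seed=0)
        assert set(table["algorithm"]) == set(DEFAULT_ALGORITHMS)
        assert list(table["f1"]) == sorted(table["f1"], reverse=True)
        assert ((0 <= table["auc"]) & (table["auc"] <= 1)).all()


def test_train_requires_two_per_class():
    X, y = synthetic_features(1, 1, seed=13)
    ts = TrainingSet(X=X, y=y, ids=np.arange(2), seed=0)
    with pytest.raises(ValueError, match="per class"):
        train(ts)
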