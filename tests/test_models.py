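import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.ensemble import RandomForestClassifier

import poolloc as pl
from poolloc.models import (
    GaussianProcessLocalizer,
    RandomForestLocalizer,
    leave_location_out_eval,
    parsimonious_analysis,
    reduce_features,
    train_classifiers,
)


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=120, centers=3, n_features=8,
                      cluster_std=0.3, random_state=0)
    # pad with pure-noise features so importance has something to discard
    rng = np.random.default_rng(0)
    X = np.hstack([X, rng.standard_normal((X.shape[0], 24))])
    return X.astype(np.float32), y


class TestForest:
    def test_separable_blobs_oob_and_test_accuracy(self, blobs):
        X, y = blobs
        f = RandomForestLocalizer(n_trees=60, random_state=0).fit(X, y)
        assert f.oob_score_ >= 0.99
        assert f.score(X, y) == 1.0
        assert len(f.oob_accuracy_curve_) == 60

    def test_same_seed_identical_predictions(self, blobs):
        X, y = blobs
        a = RandomForestLocalizer(n_trees=25, random_state=3).fit(X, y)
        b = RandomForestLocalizer(n_trees=25, random_state=3).fit(X, y)
        assert np.array_equal(a.predict(X), b.predict(X))
        assert np.array_equal(a.importances_, b.importances_)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            RandomForestLocalizer(n_trees=5).fit(X, np.zeros(10))

    def test_pure_noise_importance_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 30)).astype(np.float32)
        y = rng.integers(0, 2, size=80)
        f = RandomForestLocalizer(n_trees=40, random_state=1).fit(X, y)
        # permutation deltas fluctuate around zero for uninformative
        # features; none should look strongly important
        assert np.abs(f.importances_).max() < 0.05

    def test_informative_features_rank_first(self, blobs):
        X, y = blobs
        f = RandomForestLocalizer(n_trees=60, random_state=0).fit(X, y)
        top = np.argsort(f.importances_)[::-1][:3]
        assert set(top) <= set(range(8))   # the non-noise columns

    def test_agrees_with_sklearn_forest(self, blobs):
        X, y = blobs
        ours = RandomForestLocalizer(n_trees=60, random_state=0).fit(X, y)
        ref = RandomForestClassifier(n_estimators=60, random_state=0,
                                     oob_score=True).fit(X, y)
        assert abs(ours.oob_score_ - ref.oob_score_) < 0.05
        agree = np.mean(ours.predict(X) == ref.predict(X))
        assert agree > 0.98

    def test_subsample_mode(self, blobs):
        X, y = blobs
        f = RandomForestLocalizer(n_trees=20, bootstrap=False,
                                  subsample_fraction=0.75,
                                  random_state=0).fit(X, y)
        assert f.oob_score_ >= 0.95


class TestReduceFeatures:
    def test_all_zero_empty(self):
        assert reduce_features(np.zeros(10)).size == 0

    def test_threshold_monotonicity(self):
        imp = np.array([-0.1, 0.0, 0.01, 0.5, 0.2])
        base = reduce_features(imp)
        assert base.tolist() == [2, 3, 4]
        for t in (0.05, 0.3):
            smaller = np.flatnonzero(imp > t)
            assert set(smaller) <= set(base)


class TestClassifierSuite:
    def test_separable_all_models_perfect(self, blobs):
        X, y = blobs
        suite = train_classifiers(X[:, :8], y, seed=0)
        assert set(suite.models) == {"tree", "svm_linear",
                                     "svm_quadratic", "lda"}
        for name in suite.models:
            assert suite.cv_accuracy[name] >= 0.99, name
            assert np.mean(suite.predict(name, X[:, :8]) == y) == 1.0

    def test_tree_split_budget(self, blobs):
        X, y = blobs
        suite = train_classifiers(X, y, seed=0, max_splits=20)
        tree = suite.models["tree"]
        n_internal = np.sum(tree.tree_.children_left != -1)
        assert n_internal <= 20

    def test_prediction_range_covers_all_classes(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(-10, 10, size=(14, 5))
        y = np.repeat(np.arange(14), 12)
        X = centers[y] + 0.05 * rng.standard_normal((y.size, 5))
        suite = train_classifiers(X.astype(np.float32), y, seed=0)
        preds = suite.predict("svm_quadratic", X.astype(np.float32))
        assert set(preds) == set(range(14))

    def test_empty_feature_set_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError):
            train_classifiers(X[:, :0], y, seed=0)


class TestGPR:
    def test_interpolates_training_points(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(40, 4)).astype(np.float32)
        coords = np.column_stack([X[:, 0] * 3, X[:, 1] - 1, X[:, 2] * 0.5])
        gp = GaussianProcessLocalizer(random_state=0).fit(X, coords)
        pred = gp.predict(X)
        assert np.abs(pred - coords).max() < 0.05

    def test_constant_labels_constant_predictions(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 3)).astype(np.float32)
        coords = np.tile([1.0, 2.0, 3.0], (20, 1))
        gp = GaussianProcessLocalizer(random_state=0).fit(X, coords)
        pred = gp.predict(rng.standard_normal((5, 3)).astype(np.float32))
        assert np.allclose(pred, [1.0, 2.0, 3.0], atol=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            GaussianProcessLocalizer().fit(np.zeros((1, 2)),
                                           np.zeros((1, 3)))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    centers = rng.uniform(-5, 5, size=(4, 3))
    feats = rng.uniform(-5, 5, size=(4, 6))
    rows, coords, locs = [], [], []
    for li in range(4):
        for _ in range(10):
            rows.append(feats[li] + 0.1 * rng.standard_normal(6))
            coords.append(centers[li])
            locs.append(f"L{li}")
    X = np.asarray(rows, dtype=np.float32)
    coords = np.asarray(coords)
    locs = np.asarray(locs)
    test = np.tile([True] * 2 + [False] * 8, 4)
    return (X[~test], coords[~test], locs[~test],
            X[test], coords[test], locs[test])


class TestLeaveLocationOut:
    def test_prediction_count_and_rounds(self, toy):
        preds, rounds = leave_location_out_eval(*toy, seed=0)
        assert preds.shape == (toy[3].shape[0], 3)
        assert len(rounds) == 4
        assert np.all(np.isfinite(preds))

    def test_predictions_are_not_centroid_lookups(self, toy):
        preds, _ = leave_location_out_eval(*toy, seed=0)
        train_centroids = np.unique(toy[1], axis=0)
        for p in preds:
            assert not np.any(
                np.all(np.isclose(train_centroids, p, atol=1e-9), axis=1)
            )

    def test_missing_test_location_rejected(self, toy):
        Xtr, ctr, ltr, Xte, cte, lte = toy
        keep = lte != "L0"
        with pytest.raises(ValueError, match="L0"):
            leave_location_out_eval(Xtr, ctr, ltr,
                                    Xte[keep], cte[keep], lte[keep])


class TestParsimonious:
    def test_used_set_and_matrices(self, blobs):
        X, y = blobs
        suite = train_classifiers(X, y, seed=0, max_splits=20)
        d = X.shape[1]
        rng = np.random.default_rng(0)
        pairs = np.column_stack([rng.integers(1, 17, d),
                                 rng.integers(1, 17, d)])
        pairs = np.sort(pairs, axis=1)
        arr_of_ch = np.repeat(np.arange(4), 4)
        res = parsimonious_analysis(suite.models["tree"], X, y, pairs,
                                    arr_of_ch, seed=0, n_trees=30)
        assert res.used_indices.size <= 2 * 20 + 1
        assert np.allclose(res.pair_importance, res.pair_importance.T)
        assert np.allclose(res.array_importance, res.array_importance.T)
        assert res.pair_importance.sum() > 0

    def test_splitless_tree_rejected(self, blobs):
        X, y = blobs
        from sklearn.tree import DecisionTreeClassifier
        stump = DecisionTreeClassifier(max_depth=1).fit(
            np.zeros((10, 2)), np.zeros(10))
        with pytest.raises(ValueError):
            parsimonious_analysis(stump, X, y, np.zeros((2, 2), int),
                                  np.repeat(np.arange(4), 4))
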