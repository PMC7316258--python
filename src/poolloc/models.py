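"""Learned localizers.

The primary model is a Breiman random forest of CART trees grown on the
full ~900k-element feature set.  Its out-of-bag (OOB) accuracy is tracked
against tree count, and feature importance is measured as the *permuted
variable delta error*: the mean increase in per-tree OOB error when one
feature's values are permuted among that tree's OOB cases.  Only features
a tree actually splits on can change its predictions, so the permutation
scan runs over each tree's used-feature set — the delta is exactly zero
for all other features — which makes the computation tractable at this
feature count.  Features with strictly positive importance form the
reduced set consumed by the secondary classifiers (CART tree with a split
budget, linear/quadratic SVM, LDA) and by per-axis Gaussian-process
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from scipy.spatial.distance import pdist

__all__ = [
    "RandomForestLocalizer",
    "reduce_features",
    "ClassifierSuite",
    "train_classifiers",
    "GaussianProcessLocalizer",
    "train_gpr",
    "leave_location_out_eval",
    "ParsimoniousResult",
    "parsimonious_analysis",
]


def _as_float32(X) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=np.float32)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _tree_predict_sub(tree, Xsub: np.ndarray, col_of: np.ndarray) -> np.ndarray:
    """Predict class indices with a fitted sklearn tree on a column-subset
    matrix.  `col_of[f]` maps an original feature index to its column in
    `Xsub` (only used features need valid entries)."""
    t = tree.tree_
    node = np.zeros(Xsub.shape[0], dtype=np.intp)
    rows = np.arange(Xsub.shape[0])
    while True:
        left = t.children_left[node]
        active = left != -1
        if not active.any():
            break
        an, ar = node[active], rows[active]
        cols = col_of[t.feature[an]]
        go_left = Xsub[ar, cols] <= t.threshold[an]
        node[active] = np.where(go_left, left[active],
                                t.children_right[an])
    return np.argmax(t.value[node, 0, :], axis=1)


class RandomForestLocalizer(BaseEstimator, ClassifierMixin):
    """Bagged CART ensemble for source-location classification.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 300; OOB accuracy typically saturates far
        earlier).
    max_features : str | int | float
        Per-split feature subsampling; "sqrt" is the classification
        standard.
    bootstrap : bool
        Per-tree case sampling: bootstrap with replacement (default) or,
        if False, a `subsample_fraction` subset without replacement.
    compute_importance : bool
        Compute the permuted variable delta error on OOB cases after
        fitting (skippable for speed when only predictions are needed).

    Attributes
    ----------
    classes_ : ndarray of class labels.
    oob_accuracy_curve_ : ndarray, cumulative OOB accuracy vs tree count.
    oob_score_ : float, final OOB accuracy.
    importances_ : ndarray (n_features,), permuted variable delta error
        (unscaled mean OOB error increase).
    reduced_indices_ : ndarray, features with importance > 0.
    """

    def __init__(self, n_trees: int = 300, max_features="sqrt",
                 bootstrap: bool = True, subsample_fraction: float = 0.75,
                 compute_importance: bool = True,
                 random_state: int | None = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.subsample_fraction = subsample_fraction
        self.compute_importance = compute_importance
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_float32(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)

        self.estimators_ = []
        self._oob_masks = []
        n_classes = self.classes_.size
        votes = np.zeros((n, n_classes), dtype=np.int32)
        seen = np.zeros(n, dtype=bool)
        curve = np.empty(self.n_trees)
        for _ in range(self.n_trees):
            if self.bootstrap:
                idx = rng.integers(0, n, size=n)
            else:
                k = max(1, round(self.subsample_fraction * n))
                idx = rng.choice(n, size=k, replace=False)
            weights = np.bincount(idx, minlength=n).astype(np.float64)
            oob = weights == 0
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2 ** 31 - 1)),
            )
            # fitting on the full matrix with bootstrap counts as sample
            # weights avoids materializing a per-tree copy of X
            tree.fit(X, y_enc, sample_weight=weights, check_input=False)
            self.estimators_.append(tree)
            self._oob_masks.append(oob)
            if oob.any():
                pred = tree.predict(X, check_input=False).astype(int)
                votes[np.flatnonzero(oob), pred[oob]] += 1
                seen |= oob
            if seen.any():
                oob_pred = np.argmax(votes[seen], axis=1)
                curve[len(self.estimators_) - 1] = np.mean(
                    oob_pred == y_enc[seen]
                )
            else:
                curve[len(self.estimators_) - 1] = np.nan
        self.oob_accuracy_curve_ = curve
        self.oob_score_ = float(curve[-1])
        self.n_features_in_ = d

        if self.compute_importance:
            self.importances_ = self._permuted_delta_error(X, y_enc, rng)
            self.reduced_indices_ = reduce_features(self.importances_)
        return self

    def _permuted_delta_error(self, X, y_enc, rng) -> np.ndarray:
        """Mean over trees of the OOB error increase when one feature's
        OOB values are permuted.  Features never split on contribute 0."""
        d = X.shape[1]
        imp = np.zeros(d)
        col_of = np.zeros(d, dtype=np.intp)
        for tree, oob in zip(self.estimators_, self._oob_masks):
            if not oob.any():
                continue
            t = tree.tree_
            used = np.unique(t.feature[t.feature >= 0])
            if used.size == 0:
                continue
            Xsub = np.array(X[np.ix_(oob, used)])
            col_of[used] = np.arange(used.size)
            y_oob = y_enc[oob]
            base_err = np.mean(
                _tree_predict_sub(tree, Xsub, col_of) != y_oob
            )
            m = Xsub.shape[0]
            for c, f in enumerate(used):
                saved = Xsub[:, c].copy()
                Xsub[:, c] = saved[rng.permutation(m)]
                perm_err = np.mean(
                    _tree_predict_sub(tree, Xsub, col_of) != y_oob
                )
                Xsub[:, c] = saved
                imp[f] += perm_err - base_err
        return imp / self.n_trees

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = _as_float32(X)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=np.int32)
        for tree in self.estimators_:
            pred = tree.predict(X, check_input=False).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        return self.classes_[np.argmax(votes, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def reduce_features(importances) -> np.ndarray:
    """Indices of strictly-positive-importance features, order preserved."""
    return np.flatnonzero(np.asarray(importances) > 0)


# --------------------------------------------------------------------------
# Secondary classifiers
# --------------------------------------------------------------------------

@dataclass
class ClassifierSuite:
    """Four classifiers fitted on the reduced feature set, with their
    stratified k-fold cross-validation accuracies (fractions in [0, 1])."""

    models: dict[str, object]
    cv_accuracy: dict[str, float]

    def predict(self, name: str, X) -> np.ndarray:
        return self.models[name].predict(X)


def _scaled(est) -> Pipeline:
    # trees need no scaling; SVM/LDA get train-set z-scoring
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def train_classifiers(
    X, y, seed: int = 0, max_splits: int = 20, n_folds: int = 10
) -> ClassifierSuite:
    """Fit {CART tree (split budget), linear SVM, quadratic SVM, LDA}.

    Each model is scored with stratified k-fold cross-validation (folds
    capped at the smallest class count), then refit on all the data.  The
    tree's complexity is capped at `max_splits` internal splits to curb
    CART's tendency to overfit.
    """
    X = _as_float32(X)
    if X.shape[1] == 0:
        raise ValueError("reduced feature set is empty")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members for stratified CV")
    folds = int(min(n_folds, counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    candidates = {
        "tree": DecisionTreeClassifier(
            max_leaf_nodes=max_splits + 1, random_state=seed
        ),
        "svm_linear": _scaled(SVC(kernel="linear", C=1.0,
                                  decision_function_shape="ovo",
                                  random_state=seed)),
        "svm_quadratic": _scaled(SVC(kernel="poly", degree=2, coef0=1.0,
                                     C=1.0, decision_function_shape="ovo",
                                     random_state=seed)),
        "lda": _scaled(LinearDiscriminantAnalysis()),
    }
    models, cv_acc = {}, {}
    for name, est in candidates.items():
        scores = cross_val_score(clone(est), X, y, cv=cv, scoring="accuracy")
        cv_acc[name] = float(np.mean(scores))
        models[name] = est.fit(X, y)
    return ClassifierSuite(models, cv_acc)


# --------------------------------------------------------------------------
# Gaussian process regression
# --------------------------------------------------------------------------

class GaussianProcessLocalizer(BaseEstimator, RegressorMixin):
    """Per-axis GP regression of source coordinates (kriging).

    One independent squared-exponential-kernel GP is fitted per Cartesian
    axis on z-scored reduced features; predictions are posterior means.
    Kernel hyperparameters (signal variance, length scale, noise level)
    are fitted by marginal-likelihood maximization with a fixed restart
    seed.
    """

    def __init__(self, n_restarts: int = 1, random_state: int | None = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, coords):
        X = _as_float32(X)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training snippets")
        self.scaler_ = StandardScaler().fit(X)
        A = self.scaler_.transform(X)
        # initialize the RBF length scale at the median pairwise distance
        # of the scaled training inputs: in high dimension distances
        # concentrate far from unity, and a unit initial scale drives the
        # marginal-likelihood optimizer into the degenerate
        # predict-the-mean regime
        sub = A[:: max(1, A.shape[0] // 200)]
        d = pdist(sub)
        med = max(float(np.median(d)) if d.size else 1.0, 1e-6)
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(length_scale=med,
                        length_scale_bounds=(med / 100, med * 100))
                  + WhiteKernel(1e-2, (1e-8, 1e2)))
        self.models_ = [
            GaussianProcessRegressor(
                kernel=kernel,
                n_restarts_optimizer=self.n_restarts,
                normalize_y=True,
                random_state=self.random_state,
            ).fit(A, coords[:, ax])
            for ax in range(3)
        ]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = self.scaler_.transform(_as_float32(X))
        return np.column_stack([m.predict(X) for m in self.models_])


def train_gpr(X, coords, **params) -> GaussianProcessLocalizer:
    """Functional wrapper over `GaussianProcessLocalizer.fit`."""
    return GaussianProcessLocalizer(**params).fit(X, coords)


def leave_location_out_eval(
    X_train, coords_train, loc_train,
    X_test, coords_test, loc_test,
    seed: int = 0, n_restarts: int = 1,
):
    """Leave-one-location-out GP regression.

    For every source location: fit the 3-axis GP on training snippets
    from *all other* locations, then predict the held-out location's test
    snippets.  Returns (predictions (n_test, 3) aligned with the test
    arrays, fitted-location order).
    """
    loc_train = np.asarray(loc_train)
    loc_test = np.asarray(loc_test)
    locations = sorted(set(loc_train))
    if len(locations) < 3:
        raise ValueError("need >= 3 locations for leave-location-out")
    missing = [l for l in locations if not np.any(loc_test == l)]
    if missing:
        raise ValueError(f"locations without test snippets: {missing}")
    preds = np.full((len(loc_test), 3), np.nan)
    for loc in locations:
        keep = loc_train != loc
        model = GaussianProcessLocalizer(
            n_restarts=n_restarts, random_state=seed
        ).fit(X_train[keep], np.asarray(coords_train)[keep])
        mask = loc_test == loc
        preds[mask] = model.predict(X_test[mask])
    return preds, locations


# --------------------------------------------------------------------------
# Parsimonious-tree analysis
# --------------------------------------------------------------------------

@dataclass
class ParsimoniousResult:
    used_indices: np.ndarray          # columns of the reduced matrix
    forest: RandomForestLocalizer     # retrained on the used features only
    pair_importance: np.ndarray       # (16, 16) symmetric
    array_importance: np.ndarray      # (4, 4) symmetric
    test_accuracy: float | None = None


def parsimonious_analysis(
    tree: DecisionTreeClassifier,
    X_reduced, y,
    pairs,
    array_of_channel,
    seed: int = 0,
    n_trees: int = 300,
) -> ParsimoniousResult:
    """Map a split-budgeted tree's used features back to hydrophone pairs.

    `pairs` gives the (i, j) channel pair of each reduced-set feature
    (1-based); `array_of_channel` maps channel 1..16 to array index 0..3.
    The tree's used features form the parsimonious set; a forest is
    retrained on them, and its permuted-delta-error importances are
    summed within hydrophone pairs (16x16, symmetric) and averaged within
    array pairs (4x4, symmetric).
    """
    t = tree.tree_
    used = np.unique(t.feature[t.feature >= 0])
    if used.size == 0:
        raise ValueError("the tree used no features")
    X_used = np.ascontiguousarray(np.asarray(X_reduced)[:, used])
    forest = RandomForestLocalizer(
        n_trees=n_trees, random_state=seed
    ).fit(X_used, y)

    pairs = np.asarray(pairs)
    arr = np.asarray(array_of_channel)
    pair_imp = np.zeros((16, 16))
    for imp, f in zip(forest.importances_, used):
        i, j = pairs[f]
        w = max(imp, 0.0)
        pair_imp[i - 1, j - 1] += w
        if i != j:
            pair_imp[j - 1, i - 1] += w
    array_imp = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            cells = pair_imp[np.ix_(arr == a, arr == b)]
            array_imp[a, b] = cells.mean()
    return ParsimoniousResult(used, forest, pair_imp, array_imp)
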