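"""Random-forest resolution of undetermined variants.

The filter stage yields confidently labelled HIGH and LOW variants;
those train a 50-tree random forest over the seven sequencing-quality
features, which then assigns every undetermined variant a probability
of being high-quality.  Probabilities strictly above the threshold
(default 0.5) become HIGH, everything else LOW, so the final call set
is a clean two-way partition.

:class:`ForestVariantClassifier` follows the scikit-learn estimator
protocol (``fit`` / ``predict`` / ``predict_proba``, ``get_params``,
trailing-underscore fitted attributes) and composes with sklearn
pipelines and model selection; the module-level functions are thin
wrappers used by the CLI pipeline.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.utils.validation import check_is_fitted

from .filters import QcLabel

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingSet:
    """Class-balanced feature matrix with provenance ids.

    ``y`` is 1 for filter-stage HIGH, 0 for LOW.  After balancing the
    two classes have equal counts: the majority class is downsampled
    uniformly without replacement to the minority size, so the set holds
    twice the minority count.
    """

    X: pd.DataFrame
    y: np.ndarray
    ids: np.ndarray
    seed: int


def build_training_set(features: pd.DataFrame, labels: pd.Series | np.ndarray,
                       seed: int) -> TrainingSet:
    """Balance filter-labelled variants into a training set.

    ``labels`` holds :class:`QcLabel` or "HIGH"/"LOW" strings; rows with
    other labels are rejected.  Deterministic given ``seed``.
    """
    lab = np.asarray([l.value if isinstance(l, QcLabel) else str(l) for l in labels])
    if not set(lab) <= {"HIGH", "LOW"}:
        raise ValueError("training labels must be HIGH or LOW only")
    y = (lab == "HIGH").astype(int)
    idx_high = np.flatnonzero(y == 1)
    idx_low = np.flatnonzero(y == 0)
    if len(idx_high) == 0 or len(idx_low) == 0:
        raise ValueError(
            "filter stage produced an empty class; relax the good bounds or "
            "tighten the bad bounds so both HIGH and LOW variants exist")
    rng = np.random.default_rng(seed)
    k = min(len(idx_high), len(idx_low))
    if len(idx_high) > k:
        idx_high = np.sort(rng.choice(idx_high, size=k, replace=False))
    elif len(idx_low) > k:
        idx_low = np.sort(rng.choice(idx_low, size=k, replace=False))
    keep = np.sort(np.concatenate([idx_high, idx_low]))
    X = features.iloc[keep].reset_index(drop=True)
    return TrainingSet(X=X, y=y[keep],
                       ids=np.asarray(features.index)[keep], seed=seed)


class ForestVariantClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over the seven variant-quality features.

    Parameters
    ----------
    n_trees : int, default 50
        Number of decision trees; 50 balances accuracy and cost.
    probability_threshold : float, default 0.5
        A variant is called HIGH iff its probability of being
        high-quality is strictly greater than this.
    balance : bool, default False
        Downsample the majority class inside ``fit``; off by default so
        the estimator behaves conventionally under sklearn model
        selection (the pipeline balances explicitly via
        :func:`build_training_set`).
    random_state : int or None
        Seed for balancing and tree construction.

    Attributes
    ----------
    forest_ : fitted :class:`~sklearn.ensemble.RandomForestClassifier`
    feature_order_ : list of feature names, fixed at fit time
    feature_importances_ : impurity-decrease importances, summing to 1
    medians_ : per-feature training medians used to impute NA cells
    """

    def __init__(self, n_trees: int = 50, probability_threshold: float = 0.5,
                 balance: bool = False, random_state: int | None = None):
        self.n_trees = n_trees
        self.probability_threshold = probability_threshold
        self.balance = balance
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def _as_matrix(self, X, fit: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_order_ = list(X.columns)
            elif list(X.columns) != self.feature_order_:
                raise ValueError(
                    f"feature order mismatch: model expects {self.feature_order_}, "
                    f"got {list(X.columns)}")
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            if fit:
                self.feature_order_ = [f"x{i}" for i in range(arr.shape[1])]
            elif arr.shape[1] != len(self.feature_order_):
                raise ValueError("feature count mismatch")
        return arr

    def fit(self, X, y) -> "ForestVariantClassifier":
        arr = self._as_matrix(X, fit=True)
        y = np.asarray(y).astype(int)
        if arr.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to train")
        if self.balance:
            rng = np.random.default_rng(self.random_state)
            idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
            k = min(len(idx0), len(idx1))
            idx0 = np.sort(rng.choice(idx0, size=k, replace=False))
            idx1 = np.sort(rng.choice(idx1, size=k, replace=False))
            keep = np.sort(np.concatenate([idx0, idx1]))
            arr, y = arr[keep], y[keep]
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(arr, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        self.medians_ = med
        arr = self._impute(arr)
        constant = arr.std(axis=0) == 0
        if constant.all():
            warnings.warn("all features are constant; the forest carries no information")
        elif constant.any():
            names = [self.feature_order_[i] for i in np.flatnonzero(constant)]
            warnings.warn(f"zero-information (constant) features: {names}")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state)
        self.forest_.fit(arr, y)
        self.classes_ = self.forest_.classes_
        imp = self.forest_.feature_importances_
        s = imp.sum()
        self.feature_importances_ = imp / s if s > 0 else np.full_like(imp, 1 / len(imp))
        self.n_features_in_ = arr.shape[1]
        return self

    def _impute(self, arr: np.ndarray) -> np.ndarray:
        mask = np.isnan(arr)
        if mask.any():
            arr = arr.copy()
            arr[mask] = np.take(self.medians_, np.nonzero(mask)[1])
        return arr

    def imputed_mask(self, X) -> np.ndarray:
        """Boolean per-row flag: True where any feature was NA (imputed)."""
        arr = self._as_matrix(X, fit=False)
        return np.isnan(arr).any(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        arr = self._impute(self._as_matrix(X, fit=False))
        return self.forest_.predict_proba(arr)

    def probability_high(self, X) -> np.ndarray:
        """P(high-quality) per variant: the fraction of trees voting HIGH."""
        proba = self.predict_proba(X)
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, col]

    def predict(self, X) -> np.ndarray:
        """1 (HIGH) iff P(high) strictly exceeds the threshold, else 0.

        Ties at exactly the threshold go to LOW ("larger than" is strict).
        """
        return (self.probability_high(X) > self.probability_threshold).astype(int)

    def predict_labels(self, X) -> tuple[np.ndarray, list[QcLabel]]:
        """(probabilities, labels) for a stats/feature frame."""
        p = self.probability_high(X)
        labels = [QcLabel.HIGH if x > self.probability_threshold else QcLabel.LOW
                  for x in p]
        return p, labels


def train(ts: TrainingSet, n_trees: int = 50,
          probability_threshold: float = 0.5) -> ForestVariantClassifier:
    """Fit the forest on a balanced training set."""
    if len(ts.y) < 4 or min((ts.y == 0).sum(), (ts.y == 1).sum()) < 2:
        raise ValueError("need at least 2 variants per class to train")
    clf = ForestVariantClassifier(
        n_trees=n_trees, probability_threshold=probability_threshold,
        random_state=ts.seed)
    return clf.fit(ts.X, ts.y)


def save_model(clf: ForestVariantClassifier, path) -> None:
    """Serialize the model with enough metadata to refuse unsafe reuse."""
    check_is_fitted(clf, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": clf.get_params(),
        "feature_order": clf.feature_order_,
        "medians": clf.medians_,
        "forest": clf.forest_,
        "importances": clf.feature_importances_,
    }
    joblib.dump(payload, path)


def load_model(path, expected_feature_order: list[str] | None = None) -> ForestVariantClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    if (expected_feature_order is not None
            and payload["feature_order"] != expected_feature_order):
        raise ValueError(
            f"model was trained with feature order {payload['feature_order']}, "
            f"expected {expected_feature_order}")
    clf = ForestVariantClassifier(**payload["params"])
    clf.feature_order_ = payload["feature_order"]
    clf.medians_ = payload["medians"]
    clf.forest_ = payload["forest"]
    clf.classes_ = payload["forest"].classes_
    clf.feature_importances_ = payload["importances"]
    clf.n_features_in_ = len(clf.feature_order_)
    return clf


def merge_final_sets(filter_high: set, filter_low: set,
                     predicted: dict) -> tuple[set, set]:
    """Combine filter-stage and predicted labels into the final partition.

    ``predicted`` maps undetermined-variant ids to :class:`QcLabel`.
    The three inputs must be pairwise disjoint; the union of the outputs
    equals the union of the inputs.
    """
    pred_ids = set(predicted)
    if filter_high & filter_low or filter_high & pred_ids or filter_low & pred_ids:
        raise ValueError("filter/predicted variant sets overlap: pipeline bug")
    pred_high = {k for k, v in predicted.items() if v is QcLabel.HIGH or v == "HIGH"}
    final_high = filter_high | pred_high
    final_low = filter_low | (pred_ids - pred_high)
    return final_high, final_low


# ---------------------------------------------------------------------------
# Algorithm comparison harness


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = harmonic mean of precision and recall."""
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


DEFAULT_ALGORITHMS = {
    "random_forest": lambda seed: RandomForestClassifier(n_estimators=50, random_state=seed),
    "logistic_regression": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
    "naive_bayes": lambda seed: GaussianNB(),
}


def compare_algorithms(X, y, folds: int = 10, seed: int = 0,
                       algorithms: dict | None = None) -> pd.DataFrame:
    """Cross-validated F1 / AUC / runtime per algorithm, sorted by F1.

    Features are median-imputed once (shared across algorithms) and the
    same stratified folds are reused, so the comparison isolates the
    learner.
    """
    if algorithms is None:
        algorithms = DEFAULT_ALGORITHMS
    arr = np.asarray(X, dtype=float)
    med = np.nanmedian(arr, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(arr))
    if len(nan_rows):
        arr = arr.copy()
        arr[nan_rows, nan_cols] = med[nan_cols]
    y = np.asarray(y).astype(int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for name, factory in algorithms.items():
        model = factory(seed)
        t0 = time.perf_counter()
        proba = cross_val_predict(model, arr, y, cv=cv, method="predict_proba")[:, 1]
        elapsed = time.perf_counter() - t0
        pred = (proba > 0.5).astype(int)
        rows.append({
            "algorithm": name,
            "f1": f1_score(y, pred),
            "auc": roc_auc_score(y, proba),
            "runtime_s": elapsed,
        })
    return (pd.DataFrame(rows)
            .sort_values("f1", ascending=False)
            .reset_index(drop=True))
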