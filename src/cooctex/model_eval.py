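"""Textural-model building and stratified cross-validated evaluation.

The classifiers themselves are off-the-shelf (scikit-learn SVM with a 3rd
degree polynomial kernel; a one-hidden-layer perceptron with SGD, learning
rate 0.2 and momentum 0.8, hidden size = round((inputs + classes) / 2)); the
bespoke content of this module is the protocol around them: stratified
5-fold partitioning, per-training-fold standardization, an AdaBoost-M1
combiner that works with any base learner via weighted resampling, pooled
confusion-matrix metrics and the per-feature/per-class model vectors
(relevance, mean, standard deviation, probability distribution).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .selection import CLASS_COLUMN, SelectionResult, split_features

__all__ = [
    "TexturalModel",
    "EvalReport",
    "AdaBoostM1",
    "build_textural_model",
    "stratified_folds",
    "make_classifier",
    "evaluate",
    "summary_table",
]

CLASSIFIER_SPECS = ("svm_poly3", "mlp", "adaboost_svm", "adaboost_mlp")


# --- textural model -------------------------------------------------------


@dataclasses.dataclass
class TexturalModel:
    """Per-feature, per-class summary vectors.

    ``entries[feature][class]`` holds relevance (how many selectors retained
    the feature: 0, 1 or 2), mean, standard deviation and a normalized
    fixed-bin histogram over the pooled feature range.
    """

    bins: int
    entries: dict[str, dict[str, dict]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"bins": self.bins, "entries": self.entries}, indent=2))


def build_textural_model(
    table: pd.DataFrame, selection: SelectionResult, bins: int = 16
) -> TexturalModel:
    """Summarize each selected feature per class.

    Relevance counts the selectors (CFS subset, IG top-k) that retained the
    feature.  Histograms share bin edges across classes, computed over the
    pooled min-max range; a constant feature collapses to a single spike.
    """
    if not selection.final_set:
        raise ValidationError("selection has an empty final set")
    X, y = split_features(table)
    missing = [f for f in selection.final_set if f not in X.columns]
    if missing:
        raise ValidationError(f"selected features absent from table: {missing}")
    ig_set = set(selection.ig_selected)
    cfs_set = set(selection.cfs_subset)
    entries: dict[str, dict[str, dict]] = {}
    for feat in selection.final_set:
        col = X[feat].to_numpy(dtype=np.float64)
        lo, hi = np.nanmin(col), np.nanmax(col)
        if not np.isfinite(lo) or lo == hi:
            lo, hi = lo - 0.5, lo + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        relevance = int(feat in cfs_set) + int(feat in ig_set)
        per_class: dict[str, dict] = {}
        for cls in sorted(y.unique()):
            vals = col[(y == cls).to_numpy()]
            vals = vals[np.isfinite(vals)]
            hist, _ = np.histogram(vals, bins=edges)
            total = hist.sum()
            per_class[str(cls)] = {
                "relevance": relevance,
                "mean": float(np.mean(vals)) if vals.size else float("nan"),
                "std": float(np.std(vals)) if vals.size else float("nan"),
                "distribution": (hist / total).tolist() if total else hist.tolist(),
                "bin_edges": edges.tolist(),
            }
        entries[feat] = per_class
    return TexturalModel(bins=bins, entries=entries)


# --- folds ----------------------------------------------------------------


def stratified_folds(table: pd.DataFrame, k: int = 5, seed: int = 1):
    """Seeded stratified k-fold assignment (class proportions within +/-1)."""
    _, y = split_features(table)
    counts = y.value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValidationError(
            f"classes smaller than k={k}: {dict(too_small)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


# --- classifiers ----------------------------------------------------------


class AdaBoostM1:
    """AdaBoost-M1 with weighted resampling, usable with any base learner.

    Each round draws a bootstrap sample from the current instance weights,
    fits a clone of the base estimator, and reweights by beta = err/(1-err).
    Rounds stop early on a perfect or worse-than-chance learner.
    """

    def __init__(self, base_estimator, n_rounds: int = 10, seed: int = 1):
        self.base_estimator = base_estimator
        self.n_rounds = n_rounds
        self.seed = seed
        self.estimators_: list = []
        self.alphas_: list[float] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self.classes_ = np.unique(y)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for _ in range(self.n_rounds):
            idx = rng.choice(n, size=n, replace=True, p=w)
            est = clone(self.base_estimator)
            est.fit(X[idx], y[idx])
            pred = est.predict(X)
            err = float(w[pred != y].sum())
            if err >= 0.5:
                if not self.estimators_:
                    self.estimators_.append(est)
                    self.alphas_.append(1.0)
                break
            if err <= 1e-10:
                self.estimators_.append(est)
                self.alphas_.append(np.log(1e10))
                break
            beta = err / (1.0 - err)
            self.estimators_.append(est)
            self.alphas_.append(float(np.log(1.0 / beta)))
            w[pred == y] *= beta
            w /= w.sum()
        if not self.estimators_:  # every round rejected; fall back to one fit
            est = clone(self.base_estimator)
            est.fit(X, y)
            self.estimators_.append(est)
            self.alphas_.append(1.0)
        return self

    def _votes(self, X) -> np.ndarray:
        X = np.asarray(X)
        votes = np.zeros((len(X), len(self.classes_)))
        for est, alpha in zip(self.estimators_, self.alphas_):
            pred = est.predict(X)
            for ci, cls in enumerate(self.classes_):
                votes[pred == cls, ci] += alpha
        return votes

    def predict(self, X):
        return self.classes_[np.argmax(self._votes(X), axis=1)]

    def predict_proba(self, X):
        votes = self._votes(X)
        totals = votes.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return votes / totals


def make_classifier(spec: str, n_features: int, n_classes: int, seed: int = 1):
    """Instantiate one of the four evaluated classifiers."""
    if spec == "svm_poly3":
        return SVC(kernel="poly", degree=3, random_state=seed)
    if spec == "mlp":
        hidden = max(1, int(round((n_features + n_classes) / 2)))
        return MLPClassifier(
            hidden_layer_sizes=(hidden,),
            solver="sgd",
            learning_rate_init=0.2,
            momentum=0.8,
            max_iter=500,
            random_state=seed,
        )
    if spec == "adaboost_svm":
        return AdaBoostM1(SVC(kernel="poly", degree=3, random_state=seed), n_rounds=10, seed=seed)
    if spec == "adaboost_mlp":
        hidden = max(1, int(round((n_features + n_classes) / 2)))
        base = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            solver="sgd",
            learning_rate_init=0.2,
            momentum=0.8,
            max_iter=500,
            random_state=seed,
        )
        return AdaBoostM1(base, n_rounds=10, seed=seed)
    raise ValidationError(f"unknown classifier {spec!r}; valid: {list(CLASSIFIER_SPECS)}")


# --- evaluation -----------------------------------------------------------


@dataclasses.dataclass
class EvalReport:
    """Pooled cross-validation metrics for one classifier (rates in percent)."""

    classifier: str
    recognition_rate: float
    tp_rate: float
    tn_rate: float
    auc: float
    confusion: list[list[int]]
    fold_confusions: list[list[list[int]]]
    classes: list[str]
    seconds: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _positive_scores(clf, X, classes: np.ndarray) -> np.ndarray:
    """Continuous score for the positive (second) class on binary problems."""
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(X)
        if scores.ndim == 1:
            return scores
        return scores[:, 1]
    proba = clf.predict_proba(X)
    return proba[:, 1]


def evaluate(
    table: pd.DataFrame,
    feature_names,
    classifier_spec: str,
    k: int = 5,
    seed: int = 1,
) -> EvalReport:
    """Fit/predict per stratified fold and pool the held-out results.

    Features are z-scored on each training fold only.  The positive class for
    the TP rate and AUC is the second label in sorted order; for more than
    two classes the TP/TN rates are macro-averaged recalls and the AUC is a
    macro one-vs-rest average over softmax scores.
    """
    feature_names = list(feature_names)
    if not feature_names:
        raise ValidationError("no features to evaluate")
    X_all, y_all = split_features(table)
    missing = [f for f in feature_names if f not in X_all.columns]
    if missing:
        raise ValidationError(f"features absent from table: {missing}")
    X = X_all[feature_names].to_numpy(dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValidationError("feature matrix contains non-finite values; impute first")
    y = y_all.to_numpy(dtype=object)
    classes = np.unique(y)
    n_classes = len(classes)

    folds = stratified_folds(table, k=k, seed=seed)
    started = time.perf_counter()
    y_true_pool: list = []
    y_pred_pool: list = []
    score_pool: list = []
    fold_confusions = []
    for train_idx, test_idx in folds:
        scaler = StandardScaler().fit(X[train_idx])
        X_train = scaler.transform(X[train_idx])
        X_test = scaler.transform(X[test_idx])
        clf = make_classifier(classifier_spec, len(feature_names), n_classes, seed=seed)
        clf.fit(X_train, y[train_idx])
        pred = clf.predict(X_test)
        y_true_pool.extend(y[test_idx])
        y_pred_pool.extend(pred)
        fold_confusions.append(
            confusion_matrix(y[test_idx], pred, labels=classes).tolist()
        )
        if n_classes == 2:
            score_pool.extend(_positive_scores(clf, X_test, classes))
        else:
            if hasattr(clf, "predict_proba"):
                score_pool.extend(clf.predict_proba(X_test))
            else:
                raw = clf.decision_function(X_test)
                e = np.exp(raw - raw.max(axis=1, keepdims=True))
                score_pool.extend(e / e.sum(axis=1, keepdims=True))
    elapsed = time.perf_counter() - started

    y_true = np.asarray(y_true_pool, dtype=object)
    y_pred = np.asarray(y_pred_pool, dtype=object)
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    recognition = 100.0 * np.trace(conf) / conf.sum()
    recalls = np.divide(
        np.diag(conf),
        conf.sum(axis=1),
        out=np.zeros(n_classes, dtype=np.float64),
        where=conf.sum(axis=1) > 0,
    )
    if n_classes == 2:
        tn_rate, tp_rate = 100.0 * recalls  # positive = classes[1]
        auc = 100.0 * roc_auc_score((y_true == classes[1]).astype(int), np.asarray(score_pool))
    else:
        tp_rate = tn_rate = float(100.0 * recalls.mean())
        auc = 100.0 * roc_auc_score(
            y_true, np.asarray(score_pool), multi_class="ovr", labels=classes
        )
    return EvalReport(
        classifier=classifier_spec,
        recognition_rate=float(recognition),
        tp_rate=float(tp_rate),
        tn_rate=float(tn_rate),
        auc=float(auc),
        confusion=conf.tolist(),
        fold_confusions=fold_confusions,
        classes=[str(c) for c in classes],
        seconds=float(elapsed),
    )


def summary_table(reports) -> pd.DataFrame:
    """Summary CSV layout: classifier, recognition rate, TP/TN rates, AUC, time."""
    return pd.DataFrame(
        [
            {
                "classifier": r.classifier,
                "recognition_rate": r.recognition_rate,
                "tp_rate": r.tp_rate,
                "tn_rate": r.tn_rate,
                "auc": r.auc,
                "time_s": r.seconds,
            }
            for r in reports
        ]
    )
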