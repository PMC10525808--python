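"""Classifier benchmark: six models, two cross-validation schemes.

The 14-feature table (7 spectral features x 2 muscles) is fed to six
classifiers with fixed hyperparameters — a polynomial-kernel SVM, kNN
(k = 11, Euclidean), a J48-style decision tree, gradient-boosted trees,
logistic regression and Gaussian naive Bayes — under stratified ten-fold
cross-validation and leave-one-subject-out (LOSO) cross-validation.
Min-max normalization is applied for LR, kNN and SVM only, fitted on the
training rows of each fold.  Performance is summarised by accuracy,
F-measure, specificity, sensitivity, precision, recall and the
rank-based AUCROC, plus the 2x2 confusion matrix (rows true, columns
predicted, order [NO-RISK, RISK]).

Positive-class convention: NO-RISK is the positive class — the only
assignment under which a confusion matrix of [[238, 8], [11, 235]]
simultaneously yields sensitivity 0.967, specificity 0.955 and precision
0.956.

Ten-fold results pool the confusion matrix and out-of-fold scores over
all folds; LOSO results are reported per split and as mean +/- std.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError
from .simulate import NO_RISK, RISK
from .spectral import FEATURE_COLUMNS

CLASS_ORDER = (NO_RISK, RISK)  # confusion-matrix row/column order
POSITIVE_CLASS = NO_RISK

METRIC_NAMES = ("accuracy", "f_measure", "specificity", "sensitivity",
                "precision", "recall", "auc_roc")

MODEL_NAMES = ("SVM", "KNN", "DT", "GBT", "LR", "NB")
SCHEMES = ("tenfold", "loso")


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier with its fixed hyperparameters.

    ``inert`` records hyperparameters of the original platform that have
    no counterpart in the implementation used here (e.g. a pruning
    confidence factor when pruning is disabled); they are kept for
    provenance but do not influence the model.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)
    needs_normalization: bool = False
    inert: dict = field(default_factory=dict)


MODEL_SPECS: dict[str, ModelSpec] = {
    "SVM": ModelSpec("SVM",
                     {"kernel": "poly", "power": 1.882, "bias": 1.894,
                      "gamma": 1.495, "C": 1.0},
                     needs_normalization=True),
    "KNN": ModelSpec("KNN", {"k": 11, "metric": "euclidean"},
                     needs_normalization=True),
    "DT": ModelSpec("DT", {"min_instances_per_leaf": 2, "pruning": False},
                    inert={"confidence_factor": 0.25}),
    "GBT": ModelSpec("GBT", {"max_depth": 5, "n_models": 92,
                             "learning_rate": 0.832}),
    "LR": ModelSpec("LR", {"solver": "sag", "max_epochs": 197,
                           "epsilon": 0.005},
                    needs_normalization=True,
                    inert={"step_size": 1.886, "learning_rate": "fixed"}),
    "NB": ModelSpec("NB", {"min_std": 0.068},
                    inert={"default_probability": 0.0001,
                           "threshold_std": 0.006,
                           "max_nominal_values": 33}),
}


def _poly_kernel(gamma: float, bias: float, power: float):
    def kernel(X, Y):
        return (gamma * (X @ Y.T) + bias) ** power
    return kernel


class FlooredGaussianNB(GaussianNB):
    """Gaussian naive Bayes with a per-feature standard-deviation floor."""

    def __init__(self, min_std: float = 0.068, priors=None,
                 var_smoothing: float = 1e-9):
        super().__init__(priors=priors, var_smoothing=var_smoothing)
        self.min_std = min_std

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight=sample_weight)
        self.var_ = np.maximum(self.var_, self.min_std ** 2)
        return self


def make_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a model spec."""
    h = spec.hyperparameters
    if spec.name == "SVM":
        return SVC(C=h["C"],
                   kernel=_poly_kernel(h["gamma"], h["bias"], h["power"]))
    if spec.name == "KNN":
        return KNeighborsClassifier(n_neighbors=h["k"], metric=h["metric"])
    if spec.name == "DT":
        return DecisionTreeClassifier(criterion="entropy",
                                      min_samples_leaf=h["min_instances_per_leaf"],
                                      random_state=seed)
    if spec.name == "GBT":
        return GradientBoostingClassifier(n_estimators=h["n_models"],
                                          learning_rate=h["learning_rate"],
                                          max_depth=h["max_depth"],
                                          random_state=seed)
    if spec.name == "LR":
        return LogisticRegression(solver=h["solver"], max_iter=h["max_epochs"],
                                  tol=h["epsilon"], random_state=seed)
    if spec.name == "NB":
        return FlooredGaussianNB(min_std=h["min_std"])
    raise ParameterError(f"unknown model name {spec.name!r}")


def minmax_normalize(train_rows: np.ndarray, apply_rows: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (x - min)/(max - min) with statistics from train rows.

    Applied rows may fall outside [0, 1] (no clipping).  Zero-range
    features are mapped to 0 everywhere.
    """
    train_rows = np.asarray(train_rows, dtype=float)
    apply_rows = np.asarray(apply_rows, dtype=float)
    lo = train_rows.min(axis=0)
    span = train_rows.max(axis=0) - lo
    safe = np.where(span == 0.0, 1.0, span)
    out_train = (train_rows - lo) / safe
    out_apply = (apply_rows - lo) / safe
    zero = span == 0.0
    out_train[:, zero] = 0.0
    out_apply[:, zero] = 0.0
    return out_train, out_apply


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0
                     ) -> np.ndarray:
    """Fold assignment (0..k-1) preserving class proportions per fold."""
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ParameterError(f"class {cls!r} has fewer than k={k} rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        assignment[test_idx] = fold
    return assignment


def leave_one_subject_out(subject_ids: np.ndarray
                          ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_idx, test_idx) split per subject."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ParameterError("leave-one-subject-out needs >= 2 subjects")
    splits = []
    for s in subjects:
        test = np.flatnonzero(subject_ids == s)
        train = np.flatnonzero(subject_ids != s)
        splits.append((train, test))
    return splits


def confusion_matrix_counts(y_true: np.ndarray, y_pred: np.ndarray
                            ) -> np.ndarray:
    """2x2 counts, rows = true class, columns = predicted, order CLASS_ORDER."""
    out = np.zeros((2, 2), dtype=int)
    for i, true_cls in enumerate(CLASS_ORDER):
        for j, pred_cls in enumerate(CLASS_ORDER):
            out[i, j] = int(np.sum((y_true == true_cls)
                                   & (y_pred == pred_cls)))
    return out


def evaluate_confusion(confusion: np.ndarray) -> dict[str, float | None]:
    """Metric map from a 2x2 confusion matrix (positive class NO-RISK).

    With rows/columns ordered [NO-RISK, RISK]: TP = C[0,0], FN = C[0,1],
    FP = C[1,0], TN = C[1,1].  Metrics with zero denominators are
    reported as None.
    """
    c = np.asarray(confusion)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ParameterError("confusion must be a nonnegative 2x2 matrix")
    tp, fn = float(c[0, 0]), float(c[0, 1])
    fp, tn = float(c[1, 0]), float(c[1, 1])
    n = tp + fn + fp + tn

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    accuracy = ratio(tp + tn, n)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return {"accuracy": accuracy, "f_measure": f_measure,
            "specificity": specificity, "sensitivity": sensitivity,
            "precision": precision, "recall": sensitivity}


def auc_roc(scores: np.ndarray, labels: np.ndarray,
            positive_label: str = POSITIVE_CLASS) -> float:
    """Rank-based AUC: P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


@dataclass
class CvResult:
    """Benchmark outcome for one model under one CV scheme."""

    model: str
    scheme: str
    confusion: np.ndarray  # pooled over folds
    metrics: dict[str, float | None]  # pooled (tenfold) or mean over splits
    metrics_std: dict[str, float | None] | None = None  # loso only
    per_fold: list[dict[str, float | None]] | None = None

    def to_dict(self) -> dict:
        out = {"model": self.model, "scheme": self.scheme,
               "confusion": self.confusion.tolist(),
               "metrics": self.metrics}
        if self.metrics_std is not None:
            out["metrics_std"] = self.metrics_std
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold
        return out


def _positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive (NO-RISK) class."""
    classes = list(model.classes_)
    pos_idx = classes.index(POSITIVE_CLASS)
    if hasattr(model, "decision_function"):
        raw = model.decision_function(X)
        # Binary decision_function scores the second class in classes_.
        return raw if pos_idx == 1 else -raw
    proba = model.predict_proba(X)
    return proba[:, pos_idx]


def _run_splits(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                splits: Iterable[tuple[np.ndarray, np.ndarray]],
                seed: int) -> tuple[np.ndarray, list[np.ndarray],
                                    np.ndarray, np.ndarray]:
    """Fit/evaluate on each split; returns pooled predictions and scores."""
    y_pred = np.empty(len(y), dtype=object)
    scores = np.empty(len(y), dtype=float)
    fold_confusions = []
    for train_idx, test_idx in splits:
        X_train, X_test = X[train_idx], X[test_idx]
        if spec.needs_normalization:
            X_train, X_test = minmax_normalize(X_train, X_test)
        model = make_model(spec, seed=seed)
        model.fit(X_train, y[train_idx])
        pred = model.predict(X_test)
        y_pred[test_idx] = pred
        scores[test_idx] = _positive_scores(model, X_test)
        fold_confusions.append(confusion_matrix_counts(y[test_idx], pred))
    pooled = np.sum(fold_confusions, axis=0)
    return pooled, fold_confusions, y_pred, scores


def run_benchmark(feature_table: pd.DataFrame,
                  schemes: tuple[str, ...] = SCHEMES,
                  seed: int = 0,
                  models: tuple[str, ...] = MODEL_NAMES,
                  k: int = 10) -> list[CvResult]:
    """Benchmark the requested models under the requested CV schemes."""
    missing = [c for c in (*FEATURE_COLUMNS, "label", "subject_id")
               if c not in feature_table.columns]
    if missing:
        raise ParameterError(f"feature table missing columns: {missing}")
    table = feature_table
    if "valid" in table.columns:
        table = table[table["valid"] == True]  # noqa: E712
    X = table.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    subjects = table["subject_id"].to_numpy()

    results: list[CvResult] = []
    for scheme in schemes:
        if scheme == "tenfold":
            assignment = stratified_kfold(y, k=k, seed=seed)
            splits = [(np.flatnonzero(assignment != f),
                       np.flatnonzero(assignment == f)) for f in range(k)]
        elif scheme == "loso":
            splits = leave_one_subject_out(subjects)
        else:
            raise ParameterError(f"unknown scheme {scheme!r}")
        for name in models:
            spec = MODEL_SPECS[name]
            pooled, fold_confusions, y_pred, scores = _run_splits(
                spec, X, y, splits, seed)
            if scheme == "tenfold":
                metrics = evaluate_confusion(pooled)
                metrics["auc_roc"] = auc_roc(scores, y)
                results.append(CvResult(name, scheme, pooled, metrics))
            else:
                per_fold = []
                for conf, (_, test_idx) in zip(fold_confusions, splits):
                    m = evaluate_confusion(conf)
                    try:
                        m["auc_roc"] = auc_roc(scores[test_idx], y[test_idx])
                    except ParameterError:
                        m["auc_roc"] = None
                    per_fold.append(m)
                mean: dict[str, float | None] = {}
                std: dict[str, float | None] = {}
                for key in METRIC_NAMES:
                    vals = [m[key] for m in per_fold if m[key] is not None]
                    mean[key] = float(np.mean(vals)) if vals else None
                    std[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
                results.append(CvResult(name, scheme, pooled, mean,
                                        metrics_std=std, per_fold=per_fold))
    return results
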