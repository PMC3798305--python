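"""Classifier evaluation: confusion metrics, ROC curves and AUROC.

The abnormal class is the positive class throughout.  ROC curves are built
from continuous scores by a descending threshold sweep with equal scores
grouped into one step, so the area under the curve (trapezoidal) equals the
tie-corrected Mann-Whitney probability of correct ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TrainedClassifier, predict, train_knn, train_svm
from .cohort import ABNORMAL, TEST, TRAIN
from .screening import ScreeningResult
from .texture import FAMILY_FEATURES, FEATURE_NAMES


@dataclass
class EvalReport:
    """Confusion counts, summary rates and the ROC curve of one classifier."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc: np.ndarray      # (n, 2) array of (1-specificity, sensitivity)
    auroc: float


def confusion_metrics(y_true, y_pred) -> tuple[int, int, int, int, float, float, float]:
    """TP/FP/TN/FN plus accuracy, sensitivity and specificity (abnormal = positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label sequences must be non-empty and equal length")
    pos_t = y_true == ABNORMAL
    pos_p = y_pred == ABNORMAL
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return tp, fp, tn, fn, accuracy, sensitivity, specificity


def roc_and_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (1-specificity, sensitivity) and the trapezoidal AUROC.

    Thresholds sweep the unique scores in descending order; the curve runs
    from (0, 0) to (1, 1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == ABNORMAL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order]
    # group equal scores into single threshold steps
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(pos_sorted)[distinct]
    fps = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auroc


def make_report(y_true, y_pred, scores) -> EvalReport:
    tp, fp, tn, fn, acc, sens, spec = confusion_metrics(y_true, y_pred)
    roc, auroc = roc_and_auc(y_true, scores)
    return EvalReport(tp, fp, tn, fn, acc, sens, spec, roc, auroc)


def feature_selections(screening: ScreeningResult | None) -> dict[str, list[str]]:
    """The seven evaluated feature sets: five families, all 19, and the
    screened ('optimal') subset."""
    sel = {name: list(feats) for name, feats in FAMILY_FEATURES.items()
           if name != "FDTA"}
    sel["All"] = list(FEATURE_NAMES)
    if screening is not None:
        sel["Optimal"] = list(screening.selected)
    return sel


def _fit(kind: str, X, y, svm_kwargs: dict, knn_kwargs: dict) -> TrainedClassifier:
    if kind == "svm":
        return train_svm(X, y, **svm_kwargs)
    return train_knn(X, y, **knn_kwargs)


def evaluate_all(
    features: pd.DataFrame,
    screening: ScreeningResult | None,
    svm_kwargs: dict | None = None,
    knn_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Train and evaluate both classifiers on every feature selection.

    ``features`` is the per-ROI table with ``role`` assigning the train/test
    split.  Returns (metrics table, ROC-point table, per-sample predictions,
    reports dict keyed by (selection, classifier)).
    """
    svm_kwargs = svm_kwargs or {}
    knn_kwargs = knn_kwargs or {}
    train = features[features["role"] == TRAIN]
    test = features[features["role"] == TEST]
    if train.empty or test.empty:
        raise ValueError("both train and test roles must be populated")
    selections = feature_selections(screening)
    rows, roc_rows, pred_rows, reports = [], [], [], {}
    for sel_name, feats in selections.items():
        if not feats:
            continue
        Xtr, ytr = train[feats].to_numpy(float), train["class"].to_numpy()
        Xte, yte = test[feats].to_numpy(float), test["class"].to_numpy()
        for kind in ("svm", "knn"):
            model = _fit(kind, Xtr, ytr, svm_kwargs, knn_kwargs)
            labels, scores = predict(model, Xte)
            rep = make_report(yte, labels, scores)
            reports[(sel_name, kind)] = rep
            rows.append({
                "feature_set": sel_name, "n_features": len(feats),
                "classifier": kind, "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                "auroc": rep.auroc,
            })
            for fpr, tpr in rep.roc:
                roc_rows.append({"feature_set": sel_name, "classifier": kind,
                                 "fpr": fpr, "tpr": tpr})
            for subj, yt, yp, sc in zip(test["subject"], yte, labels, scores):
                pred_rows.append({"feature_set": sel_name, "classifier": kind,
                                  "subject": subj, "true": yt,
                                  "predicted": yp, "score": sc})
    return (pd.DataFrame(rows), pd.DataFrame(roc_rows),
            pd.DataFrame(pred_rows), reports)
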