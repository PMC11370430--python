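"""Classifier evaluation: accuracy, ROC, AUC, confusion counts."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


@dataclass
class EvalReport:
    accuracy: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    confusion: np.ndarray            # (true, predicted)
    train_acc: list = dc_field(default_factory=list)
    val_acc: list = dc_field(default_factory=list)

    def summary(self) -> str:
        tn, fp, fn, tp = self.confusion.ravel()
        return (f"accuracy={self.accuracy:.4f}  AUC={self.auc:.4f}  "
                f"confusion=[tn={tn} fp={fp} fn={fn} tp={tp}]")


def roc_curve_points(scores: np.ndarray, y: np.ndarray):
    """ROC over all score thresholds (positive class = 1).

    Returns (fpr, tpr, thresholds), both monotone non-decreasing from
    (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    P = max((y == 1).sum(), 1)
    N = max((y == 0).sum(), 1)
    # collapse ties: keep the last index of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / P]
    fpr = np.r_[0.0, fps[distinct] / N]
    thr = np.r_[np.inf, scores[order][distinct]]
    return fpr, tpr, thr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def evaluate_classifier(model, X_test, y_test,
                        positive_class: int = 1) -> EvalReport:
    """Held-out evaluation; the ROC positive class defaults to index 1
    (the stiffer phenotype under sorted labels)."""
    if len(X_test) == 0:
        raise ValueError("empty test split")
    proba = model.predict_proba(X_test)
    pred = proba.argmax(axis=1)
    acc = float((pred == y_test).mean())
    scores = proba[:, positive_class]
    y_bin = (y_test == positive_class).astype(int)
    fpr, tpr, thr = roc_curve_points(scores, y_bin)
    auc = auc_trapezoid(fpr, tpr)
    n_cls = proba.shape[1]
    conf = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(y_test, pred):
        conf[t, p] += 1
    hist = getattr(model, "history", {})
    return EvalReport(accuracy=acc, auc=auc, fpr=fpr, tpr=tpr,
                      thresholds=thr, confusion=conf,
                      train_acc=list(hist.get("train_acc", [])),
                      val_acc=list(hist.get("val_acc", [])))
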