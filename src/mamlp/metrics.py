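"""Evaluation: confusion matrix, per-class F1, macro F1, rank-count AUC.

Macro F1 is the unweighted mean of the three per-class F1 scores.  The AUC
for binary tasks is the rank-count form: the fraction of (positive,
negative) score pairs in which the positive sample outscores the negative
one, with ties worth half a pair (the Mann-Whitney convention; a strict
mode that gives ties no credit is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import CLASS_NAMES, CLASS_TO_INDEX, FeatureMatrix

#: Binary task -> (class pair); the later-listed class is scored as positive.
BINARY_TASKS = {
    "nc-mci": (0, 1),
    "nc-ad": (0, 2),
    "mci-ad": (1, 2),
}
TASKS = ("nc-mci-ad", *BINARY_TASKS)


def confusion(true_labels, predicted_labels, n_classes: int = 3) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    if t.size and (min(t.min(), p.min()) < 0
                   or max(t.max(), p.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def precision_recall_f1(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision, recall and F1; 0/0 cases resolve to 0."""
    cm = np.asarray(cm, dtype=float)
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    if np.any((col == 0) | (row == 0)):
        warnings.warn("a class has no predictions or no true samples; "
                      "its precision/recall/F1 is reported as 0",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return precision, recall, f1


def f1_per_class(cm: np.ndarray) -> np.ndarray:
    return precision_recall_f1(cm)[2]


def macro_f1(cm: np.ndarray) -> float:
    """Unweighted mean of per-class F1 scores."""
    return float(np.mean(f1_per_class(cm)))


def rank_auc(pos_scores: Sequence[float], neg_scores: Sequence[float],
             ties: str = "half") -> float:
    """Rank-count AUC: pairs where the positive outscores the negative,
    over all |pos| x |neg| pairs.

    ``ties="half"`` (default) credits tied pairs 0.5; ``ties="strict"``
    counts only strict wins.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if ties not in ("half", "strict"):
        raise ValueError("ties must be 'half' or 'strict'")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0)
    if ties == "half":
        wins = wins + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


@dataclass
class MetricsReport:
    """Bundle of evaluation quantities for one task."""

    task: str
    confusion_matrix: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    class_names: tuple[str, ...] = CLASS_NAMES
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "class_names": list(self.class_names),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def report_from_confusion(cm: np.ndarray, task: str = "nc-mci-ad",
                          class_names=CLASS_NAMES,
                          auc: Optional[float] = None) -> MetricsReport:
    cm = np.asarray(cm)
    precision, recall, f1 = precision_recall_f1(cm)
    total = cm.sum()
    return MetricsReport(
        task=task, confusion_matrix=cm,
        accuracy=float(np.trace(cm) / total) if total else 0.0,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        class_names=tuple(class_names), auc=auc,
    )


def evaluate(model, matrix: FeatureMatrix, registry=None,
             task: str = "nc-mci-ad") -> MetricsReport:
    """Evaluate a fitted ensemble on a labelled matrix.

    The three-class task reports accuracy and macro precision/recall/F1.
    Binary tasks restrict samples to the two named classes, predict by the
    larger of the two summed-softmax scores, and add the rank-count AUC with
    the later-listed (more progressed) class as positive, scored by its
    summed-softmax entry divided by the number of subnets.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if matrix.labels is None:
        raise ValueError("evaluation needs labelled samples")
    y = matrix.labels
    if task == "nc-mci-ad":
        pred = model.predict(matrix.values)
        cm = confusion(y, pred)
        return report_from_confusion(cm, task=task)

    neg_k, pos_k = BINARY_TASKS[task]
    names = (CLASS_NAMES[neg_k], CLASS_NAMES[pos_k])
    extra = set(np.unique(y)) - {neg_k, pos_k}
    if extra:
        raise ValueError(
            f"task {task!r} admits only classes {names}; found class "
            f"code(s) {sorted(extra)} in the labels"
        )
    if not ({neg_k, pos_k} <= set(np.unique(y))):
        raise ValueError(
            f"task {task!r} needs samples of both classes {names}"
        )
    proba = model.predict_proba(matrix.values)  # summed scores / n_subnets
    pred_bin = (proba[:, pos_k] > proba[:, neg_k]).astype(int)
    y_bin = (y == pos_k).astype(int)
    cm = confusion(y_bin, pred_bin, n_classes=2)
    auc = rank_auc(proba[y_bin == 1, pos_k], proba[y_bin == 0, pos_k])
    return report_from_confusion(cm, task=task, class_names=names, auc=auc)
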