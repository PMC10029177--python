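"""Performance metrics: ROC/AUC, confusion-matrix summaries, model
evaluation reports and side-by-side tool comparison tables.

AUC is computed from midranks, so it equals the Mann-Whitney statistic
U/(n1·n2) exactly, including under ties, and is invariant to any strictly
increasing transform of the scores. Multiclass AUC is one-vs-rest per
class from that class's predicted probability.

Degenerate metrics (zero denominators — e.g. precision with no predicted
positives, or a class absent from the truth) are reported as 0.0 with an
explicit flag instead of raising, so batch comparison tables never abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import Label


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic (midrank ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d sequences")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """FPR/TPR/threshold points of the trapezoidal ROC curve (for export)."""
    fpr, tpr, thr = _sk_roc_curve(np.asarray(labels).astype(int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    precision: float
    f1: float
    accuracy: float
    support: int
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("sensitivity", "specificity", "balanced_accuracy",
              "precision", "f1", "accuracy", "support")}
        d["degenerate"] = list(self.degenerate)
        return d


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def confusion_metrics(pred: Sequence, true: Sequence, positive_class) -> ClassMetrics:
    """One-vs-rest confusion summary for one positive class."""
    pred = np.asarray(pred, dtype=object)
    true = np.asarray(true, dtype=object)
    if len(pred) != len(true):
        raise ValueError("prediction/truth length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    p = pred == positive_class
    t = true == positive_class
    tp = int(np.sum(p & t)); fn = int(np.sum(~p & t))
    fp = int(np.sum(p & ~t)); tn = int(np.sum(~p & ~t))
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "no_positives_in_truth", flags)
    spec = _safe_div(tn, tn + fp, "no_negatives_in_truth", flags)
    prec = _safe_div(tp, tp + fp, "no_predicted_positives", flags)
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1_undefined", flags)
    acc = (tp + tn) / len(pred)
    return ClassMetrics(sens, spec, (sens + spec) / 2.0, prec, f1, acc,
                        tp + fn, flags)


@dataclass
class EvaluationReport:
    task: str
    classes: list[str]
    accuracy: float
    per_class_auc: dict[str, Optional[float]]
    per_class: dict[str, ClassMetrics]
    confusion: pd.DataFrame  # rows true class, columns predicted class
    roc: dict[str, pd.DataFrame]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": self.classes,
            "accuracy": self.accuracy,
            "per_class_auc": self.per_class_auc,
            "per_class": {c: m.to_dict() for c, m in self.per_class.items()},
            "confusion": self.confusion.to_numpy().tolist(),
        }


def report_from_predictions(pred_labels: Sequence, true_labels: Sequence,
                            classes: Sequence, task: str = "external",
                            probs: Optional[np.ndarray] = None) -> EvaluationReport:
    """Build a report from hard labels (e.g. an external tool's output
    table); probabilities, when given, add per-class one-vs-rest AUC."""
    classes = [c.value if isinstance(c, Label) else str(c) for c in classes]
    pred = np.array([c.value if isinstance(c, Label) else str(c)
                     for c in pred_labels], dtype=object)
    true = np.array([c.value if isinstance(c, Label) else str(c)
                     for c in true_labels], dtype=object)
    if len(pred) == 0:
        raise ValueError("empty predictions")
    unknown = set(true) - set(classes)
    if unknown:
        raise ValueError(f"truth labels outside class alphabet: {sorted(unknown)}")
    per_class, aucs, roc = {}, {}, {}
    for j, c in enumerate(classes):
        per_class[c] = confusion_metrics(pred, true, c)
        truth = (true == c).astype(int)
        if probs is not None and 0 < truth.sum() < len(truth):
            aucs[c] = roc_auc(probs[:, j], truth)
            roc[c] = roc_points(probs[:, j], truth)
        else:
            aucs[c] = None
            if probs is not None:
                per_class[c].degenerate.append("class_absent_auc_undefined")
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    return EvaluationReport(task, list(classes), float(np.mean(pred == true)),
                            aucs, per_class, conf, roc)


def evaluate_model(model, matrix, labels: Sequence[Label]) -> EvaluationReport:
    """Full test-set report for a trained model: top-1 accuracy, one-vs-rest
    AUC per class, per-class confusion metrics and ROC points."""
    from .model import predict  # local import avoids a module cycle
    probs, pred = predict(model, matrix)
    return report_from_predictions(pred, [Label(l) for l in labels],
                                   model.classes, model.task.task, probs)


_METRIC_COLS = ("balanced_accuracy", "sensitivity", "specificity", "f1", "precision")


def compare_models(report_a: EvaluationReport, report_b: EvaluationReport,
                   name_a: str = "a", name_b: str = "b") -> pd.DataFrame:
    """Aligned per-class metric table with a winner mark per cell pair.

    The ``best`` column holds the better tool per (class, metric), or ""
    on ties."""
    if list(report_a.classes) != list(report_b.classes):
        raise ValueError("reports have different class alphabets")
    rows = []
    for c in report_a.classes:
        ma, mb = report_a.per_class[c], report_b.per_class[c]
        for metric in _METRIC_COLS:
            va, vb = getattr(ma, metric), getattr(mb, metric)
            best = "" if va == vb else (name_a if va > vb else name_b)
            rows.append((c, metric, va, vb, best))
    return pd.DataFrame(rows, columns=["class", "metric", name_a, name_b, "best"])
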