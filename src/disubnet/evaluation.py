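"""Confusion matrices and the accuracy/precision/recall/F1 metric suite.

Metrics follow the per-class true/false positive/negative reduction of a
C-class confusion matrix:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

aggregated under an explicit averaging scheme.  Micro averaging pools the
per-class counts first; for a single-label multiclass problem this makes
precision = recall = accuracy identically, which is why most published
metric rows show four equal values.  Macro averages the per-class metrics
unweighted; weighted averages them by class support.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_thermal import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "evaluate",
    "format_metric_row",
]

SCHEMES = ("micro", "macro", "weighted")


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be square over the class set")
        if (m < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...] = CLASS_NAMES) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = samples of true class i predicted j.

    Labels may be class names or integer indices into ``classes``.
    """
    def to_idx(v):
        if isinstance(v, (int, np.integer)):
            if not 0 <= v < len(classes):
                raise ValueError(f"label index {v} out of range")
            return int(v)
        try:
            return classes.index(v)
        except ValueError:
            raise ValueError(f"unknown label {v!r}") from None

    ti = np.array([to_idx(v) for v in y_true])
    pi = np.array([to_idx(v) for v in y_pred])
    if ti.shape != pi.shape:
        raise ValueError("y_true and y_pred lengths differ")
    m = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(m, (ti, pi), 1)
    return ConfusionMatrix(m, classes)


@dataclass(frozen=True)
class EvalReport:
    """Aggregated metrics (fractions in [0, 1]) plus loss and the matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    scheme: str
    loss: float
    confusion: ConfusionMatrix

    def as_percent(self) -> dict[str, str]:
        """Percentages to four decimals, the convention of the published tables."""
        return {k: f"{getattr(self, k) * 100:.4f}"
                for k in ("accuracy", "precision", "recall", "f1")}

    def to_frame(self) -> pd.DataFrame:
        """Single-row frame (CSV-ready) of the aggregated metrics and loss."""
        return pd.DataFrame([{
            "scheme": self.scheme, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "loss": self.loss,
        }])

    def to_json(self) -> str:
        return json.dumps({
            "scheme": self.scheme,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "loss": self.loss,
            "confusion": self.confusion.counts.tolist(),
            "classes": list(self.confusion.classes),
        }, indent=2)


def _safe_div(num, den, what: str):
    num, den = np.asarray(num, dtype=float), np.asarray(den, dtype=float)
    bad = den == 0
    if np.any(bad):
        warnings.warn(f"{what} undefined for {int(np.sum(bad))} class(es); reported as 0",
                      RuntimeWarning, stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return out


def metrics_from_confusion(cm: ConfusionMatrix, scheme: str = "micro",
                           loss: float = float("nan")) -> EvalReport:
    """Reduce a confusion matrix to aggregated metrics under ``scheme``.

    Classes with zero support (recall) or zero predictions (precision) are
    scored 0 with a warning; this only affects degenerate predictors.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    m = np.asarray(cm.counts, dtype=np.int64)
    if m.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m).astype(float)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    support = m.sum(axis=1)
    accuracy = float(tp.sum() / m.sum())

    if scheme == "micro":
        precision = float(_safe_div(tp.sum(), tp.sum() + fp.sum(), "micro precision"))
        recall = float(_safe_div(tp.sum(), tp.sum() + fn.sum(), "micro recall"))
        f1 = (0.0 if precision + recall == 0
              else 2 * precision * recall / (precision + recall))
    else:
        prec_c = _safe_div(tp, tp + fp, "precision")
        rec_c = _safe_div(tp, tp + fn, "recall")
        f1_c = _safe_div(2 * prec_c * rec_c, prec_c + rec_c, "F1")
        if scheme == "macro":
            precision, recall, f1 = (float(prec_c.mean()), float(rec_c.mean()),
                                     float(f1_c.mean()))
        else:
            w = support / support.sum()
            precision, recall, f1 = (float(prec_c @ w), float(rec_c @ w), float(f1_c @ w))
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                      scheme=scheme, loss=loss, confusion=cm)


def evaluate(model, x: np.ndarray, y: np.ndarray, scheme: str = "micro",
             classes: tuple[str, ...] = CLASS_NAMES,
             batch_size: int = 64) -> EvalReport:
    """Predict with argmax (ties to the lowest class index) and score.

    ``model`` is any object with a ``predict_proba(x, batch_size)`` method;
    loss is the clipped categorical cross-entropy on the same split.
    """
    if x.shape[0] == 0:
        raise ValueError("empty evaluation split")
    from .training import PredictionBatch, categorical_cross_entropy, one_hot

    probs = model.predict_proba(x, batch_size)
    loss = categorical_cross_entropy(PredictionBatch(one_hot(y, probs.shape[1]), probs))
    pred = probs.argmax(axis=1)
    cm = confusion_matrix(y.tolist(), pred.tolist(), classes)
    return metrics_from_confusion(cm, scheme, loss=loss)


def format_metric_row(model_name: str, report: EvalReport) -> str:
    """One row in the published comparison-table style (percent, 4 decimals)."""
    p = report.as_percent()
    return (f"{model_name:<16}{p['accuracy']:>10}{p['precision']:>10}"
            f"{p['recall']:>10}{p['f1']:>10}{report.loss:>10.4f}")
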