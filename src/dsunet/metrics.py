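"""Confusion-matrix metrics, macro/weighted averaging, and fold aggregation.

All metrics are reported in percent.  Per-class precision, recall and F1
are computed one-vs-rest from the 2x2 confusion matrix (rows = true class,
columns = predicted class, class order benign, malignant):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

The weighted average of a metric is sum_i (n_i / N) * metric_i with n_i the
class supports; the macro average is the unweighted class mean.  The two
coincide exactly on balanced supports.  Cross-validation results are
aggregated by the arithmetic mean of each per-class metric across folds,
and an overall row as the mean of the two per-class averages; displayed
values are rounded to 3 decimals (improvement deltas to 2) while raw
unrounded values are retained in the JSON serialization.

Division-by-zero convention: a vanishing denominator yields 0 with a
``RuntimeWarning``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CLASSES",
    "METRIC_NAMES",
    "confusion_matrix",
    "class_metrics",
    "average_metrics",
    "ClassMetrics",
    "MetricsReport",
    "aggregate_folds",
    "improvement_report",
]

CLASSES = ("benign", "malignant")
METRIC_NAMES = ("precision", "recall", "f1")


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str]) -> np.ndarray:
    """Exact 2x2 count table; rows = true class, columns = predicted."""
    if len(y_true) != len(y_pred):
        raise InvalidInputError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise InvalidInputError(f"unknown label in ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


@dataclasses.dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 in percent, plus the class support."""

    precision: float
    recall: float
    f1: float
    support: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as its inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: np.ndarray) -> tuple[dict[str, ClassMetrics], float]:
    """One-vs-rest metrics per class and overall accuracy, in percent."""
    cm = np.asarray(cm)
    if cm.shape != (2, 2) or cm.sum() == 0:
        raise InvalidInputError("confusion matrix must be 2x2 and non-empty")
    if (cm < 0).any():
        raise InvalidInputError("confusion-matrix counts must be >= 0")
    out: dict[str, ClassMetrics] = {}
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        fp = cm[1 - i, i]
        fn = cm[i, 1 - i]
        precision = 100.0 * _safe_div(tp, tp + fp, f"precision[{cls}]")
        recall = 100.0 * _safe_div(tp, tp + fn, f"recall[{cls}]")
        out[cls] = ClassMetrics(precision=precision, recall=recall,
                                f1=f1_score(precision, recall),
                                support=int(cm[i].sum()))
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    return out, float(accuracy)


def average_metrics(values: Sequence[float], supports: Sequence[float],
                    mode: str) -> float:
    """Macro (unweighted) or weighted (support-weighted) class average."""
    values = np.asarray(values, dtype=np.float64)
    supports = np.asarray(supports, dtype=np.float64)
    if values.shape != supports.shape or values.size == 0:
        raise InvalidInputError("values and supports must be equal-length, non-empty")
    if (supports < 0).any() or supports.sum() == 0:
        raise InvalidInputError("supports must be >= 0 and not all zero")
    if mode == "macro":
        return float(values.mean())
    if mode == "weighted":
        return float((values * supports).sum() / supports.sum())
    raise InvalidInputError(f"unknown averaging mode {mode!r}")


@dataclasses.dataclass
class MetricsReport:
    """Per-class metrics, accuracy, and macro/weighted averages for one fold."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    fold: int | str | None = None

    def averages(self, mode: str) -> dict[str, float]:
        supports = [self.per_class[c].support for c in CLASSES]
        return {m: average_metrics([getattr(self.per_class[c], m) for c in CLASSES],
                                   supports, mode)
                for m in METRIC_NAMES}

    @property
    def macro(self) -> dict[str, float]:
        return self.averages("macro")

    @property
    def weighted(self) -> dict[str, float]:
        return self.averages("weighted")

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "per_class": {c: self.per_class[c].as_dict() for c in CLASSES},
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricsReport":
        per_class = {c: ClassMetrics(**{k: d["per_class"][c][k]
                                        for k in ("precision", "recall", "f1", "support")})
                     for c in CLASSES}
        return cls(per_class=per_class, accuracy=d["accuracy"], fold=d.get("fold"))

    @classmethod
    def from_predictions(cls, y_true: Sequence[str], y_pred: Sequence[str],
                         fold=None) -> "MetricsReport":
        per_class, accuracy = class_metrics(confusion_matrix(y_true, y_pred))
        return cls(per_class=per_class, accuracy=accuracy, fold=fold)

    @classmethod
    def from_values(cls, benign: Sequence[float], malignant: Sequence[float],
                    accuracy: float, supports: Sequence[int] = (1, 1),
                    fold=None) -> "MetricsReport":
        """Build a report directly from (precision, recall, f1) triples."""
        per_class = {
            "benign": ClassMetrics(*benign, support=int(supports[0])),
            "malignant": ClassMetrics(*malignant, support=int(supports[1])),
        }
        return cls(per_class=per_class, accuracy=accuracy, fold=fold)


def aggregate_folds(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean per class per metric across folds.

    Returns a report whose per-class entries are the fold means and whose
    ``overall`` mapping is the mean of the two per-class averages; its
    accuracy is the mean of the fold accuracies.
    """
    if len(reports) == 0:
        raise InvalidInputError("need at least one fold report")
    for r in reports:
        if set(r.per_class) != set(CLASSES):
            raise InvalidInputError("inconsistent class sets across folds")
    per_class = {}
    for c in CLASSES:
        per_class[c] = ClassMetrics(
            precision=float(np.mean([r.per_class[c].precision for r in reports])),
            recall=float(np.mean([r.per_class[c].recall for r in reports])),
            f1=float(np.mean([r.per_class[c].f1 for r in reports])),
            support=int(np.sum([r.per_class[c].support for r in reports])),
        )
    accuracy = float(np.mean([r.accuracy for r in reports]))
    agg = MetricsReport(per_class=per_class, accuracy=accuracy, fold="average")
    return agg


def overall_row(aggregate: MetricsReport) -> dict[str, float]:
    """Mean of the two per-class averages (the summary 'Overall' row)."""
    return {m: float(np.mean([getattr(aggregate.per_class[c], m) for c in CLASSES]))
            for m in METRIC_NAMES}


def rounded_table(aggregate: MetricsReport, decimals: int = 3) -> dict:
    """Display view: per-class averages, overall row, accuracy (rounded)."""
    table = {c: {m: round(getattr(aggregate.per_class[c], m), decimals)
                 for m in METRIC_NAMES} for c in CLASSES}
    table["overall"] = {m: round(v, decimals) for m, v in overall_row(aggregate).items()}
    table["accuracy"] = round(aggregate.accuracy, decimals)
    return table


def improvement_report(a: MetricsReport, b: MetricsReport,
                       decimals: int = 2) -> dict:
    """Per-metric deltas b - a in percentage points, rounded to 2 decimals."""
    if set(a.per_class) != set(b.per_class):
        raise InvalidInputError("reports have mismatched structure")
    deltas: dict = {}
    for c in CLASSES:
        deltas[c] = {m: round(getattr(b.per_class[c], m) - getattr(a.per_class[c], m),
                              decimals)
                     for m in METRIC_NAMES}
    oa, ob = overall_row(a), overall_row(b)
    deltas["overall"] = {m: round(ob[m] - oa[m], decimals) for m in METRIC_NAMES}
    deltas["overall"]["accuracy"] = round(b.accuracy - a.accuracy, decimals)
    return deltas
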