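"""Multiclass evaluation: one-vs-rest confusion counts, the standard metric
set (accuracy, macro precision/recall/F1, per-class sensitivity, specificity,
MCC), and a stratified k-fold cross-validation driver.

Accuracy is the fraction of correct multiclass predictions (the pooled
one-vs-rest form double-counts and is not what a multiclass accuracy
conventionally reports).  Per-class metrics with an undefined denominator
are reported as 0 and flagged, since few-shot query sets can miss classes
entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "cross_validate",
    "aggregate_reports",
    "write_metrics_json",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts per class; tp+fp+fn+tn = n for every class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], num_classes: int
) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    tp = np.zeros(num_classes, dtype=int)
    fp = np.zeros(num_classes, dtype=int)
    fn = np.zeros(num_classes, dtype=int)
    tn = np.zeros(num_classes, dtype=int)
    for c in range(num_classes):
        is_c = y_true == c
        pred_c = y_pred == c
        tp[c] = int(np.sum(is_c & pred_c))
        fp[c] = int(np.sum(~is_c & pred_c))
        fn[c] = int(np.sum(is_c & ~pred_c))
        tn[c] = int(np.sum(~is_c & ~pred_c))
    return ConfusionCounts(tp, fp, fn, tn)


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray  # per class; == sensitivity
    f1: np.ndarray  # per class
    specificity: np.ndarray  # per class
    mcc: np.ndarray  # per class, in [-1, 1]
    macro_f1: float
    macro_recall: float
    class_names: list[str] | None = None
    #: classes whose precision/recall/etc. hit a zero denominator
    undefined_flags: dict[str, list[int]] = field(default_factory=dict)

    @property
    def sensitivity(self) -> np.ndarray:
        return self.recall

    def to_dict(self) -> dict:
        names = self.class_names or [str(i) for i in range(len(self.precision))]
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "per_class": {
                name: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "sensitivity": float(self.recall[i]),
                    "specificity": float(self.specificity[i]),
                    "mcc": float(self.mcc[i]),
                }
                for i, name in enumerate(names)
            },
            "undefined_flags": self.undefined_flags,
        }


def _safe_divide(num: np.ndarray, den: np.ndarray, flags: list[int]) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    for i in range(len(num)):
        if den[i] == 0:
            flags.append(i)
        else:
            out[i] = num[i] / den[i]
    return out


def compute_metrics(
    counts: ConfusionCounts, class_names: Sequence[str] | None = None
) -> MetricsReport:
    """Accuracy, macro F1/recall, and per-class sensitivity/specificity/MCC.

    Macro F1 averages the per-class harmonic means of precision and recall;
    macro recall averages per-class recalls; sensitivity is recall by
    definition.  MCC uses the standard binary formula on each class's
    one-vs-rest counts.
    """
    tp, fp, fn, tn = (a.astype(float) for a in (counts.tp, counts.fp, counts.fn, counts.tn))
    flags: dict[str, list[int]] = {"precision": [], "recall": [], "f1": [],
                                   "specificity": [], "mcc": []}
    precision = _safe_divide(tp, tp + fp, flags["precision"])
    recall = _safe_divide(tp, tp + fn, flags["recall"])
    f1 = _safe_divide(2.0 * precision * recall, precision + recall, flags["f1"])
    specificity = _safe_divide(tn, tn + fp, flags["specificity"])
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_divide(tp * tn - fp * fn, mcc_den, flags["mcc"])
    total = counts.total
    accuracy = float(tp.sum() / total) if total else 0.0
    report = MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        mcc=mcc,
        macro_f1=float(f1.mean()),
        macro_recall=float(recall.mean()),
        class_names=list(class_names) if class_names is not None else None,
        undefined_flags={k: v for k, v in flags.items() if v},
    )
    return report


def cross_validate(
    labels: Sequence[str] | np.ndarray,
    model_spec: Callable[[np.ndarray, np.ndarray, int], MetricsReport],
    folds: int = 10,
    seed: int = 0,
) -> tuple[list[MetricsReport], dict[str, dict[str, float]]]:
    """Stratified k-fold driver around an arbitrary fit-and-score callable.

    ``model_spec(train_indices, test_indices, fold_seed)`` trains on the
    first index set and returns a :class:`MetricsReport` for the second.
    Returns the per-fold reports and mean +/- sd aggregates of the scalar
    metrics.  Fold assignment is deterministic under ``seed``; a class with
    fewer members than ``folds`` is an error.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.array([str(l) for l in labels])
    counts = {c: int(np.sum(y == c)) for c in set(y)}
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValueError(f"classes smaller than folds={folds}: {sorted(small)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        reports.append(model_spec(train_idx, test_idx, seed + fold))
    return reports, aggregate_reports(reports)


def aggregate_reports(
    reports: Sequence[MetricsReport],
) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of each scalar metric across folds."""
    out: dict[str, dict[str, float]] = {}
    for metric in ("accuracy", "macro_f1", "macro_recall"):
        values = np.array([getattr(r, metric) for r in reports], dtype=float)
        out[metric] = {"mean": float(values.mean()), "sd": float(values.std(ddof=0))}
    return out


def write_metrics_json(
    report: MetricsReport, path: str | Path, extra: dict | None = None
) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
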