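"""Confusion-matrix metrics and cross-validation planning.

Per-class one-vs-rest counts feed the standard scores

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 P R / (P + R),

with the zero-denominator convention metric = 0 (a warning is logged,
never a NaN).  Aggregation is macro by default, micro on request.

Cross-validation plans come in two flavours: record-wise (a seeded shuffle
of the records, fold sizes within one of each other) and subject-wise (all
records of a patient share a fold, so no subject leaks between train and
test — the stricter protocol for multi-slice medical data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVPlan",
    "confusion_counts",
    "classification_metrics",
    "crossval_split",
    "psnr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN/TN arrays (length n_classes)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate scores, all in [0, 1]."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
            "per_class": {
                "precision": list(map(float, self.precision)),
                "recall": list(map(float, self.recall)),
                "f1": list(map(float, self.f1)),
            },
        }


@dataclass(frozen=True)
class CVPlan:
    """k disjoint test folds covering every record exactly once."""

    folds: list
    k: int
    mode: str
    seed: int


def confusion_counts(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D")
    if yt.size and (min(yt.min(), yp.min()) < 0
                    or max(yt.max(), yp.max()) >= n_classes):
        raise ValueError("labels out of range")
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    tn = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        tp[c] = int(np.sum((yt == c) & (yp == c)))
        fp[c] = int(np.sum((yt != c) & (yp == c)))
        fn[c] = int(np.sum((yt == c) & (yp != c)))
        tn[c] = int(np.sum((yt != c) & (yp != c)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num, den, what: str):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    if np.any(~nz):
        logger.warning("zero denominator in %s; metric set to 0", what)
    return out


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from one-vs-rest counts."""
    total = c.tp + c.fp + c.fn + c.tn
    accuracy = float(np.sum(c.tp) / total[0]) if total[0] else 0.0
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    micro_p = _safe_div(c.tp.sum(), (c.tp + c.fp).sum(), "micro precision")
    micro_r = _safe_div(c.tp.sum(), (c.tp + c.fn).sum(), "micro recall")
    micro_f = _safe_div(2.0 * micro_p * micro_r, micro_p + micro_r,
                        "micro f1")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f),
    )


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Scores for a single positive class (direct evaluation of the formulas)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc = (tp + tn) / (tp + fp + fn + tn) if tp + fp + fn + tn else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"accuracy": acc, "precision": p, "recall": r, "f1": f1}


def crossval_split(record_ids, subject_ids=None, k: int = 10,
                   mode: str = "record", seed: int = 0) -> CVPlan:
    """Build a k-fold plan over records.

    Record mode: seeded shuffle, fold sizes differing by at most one.
    Subject mode: subjects are shuffled and assigned greedily to the
    currently smallest fold, so all records of a subject share a test fold.
    """
    records = np.asarray(record_ids)
    n = len(records)
    idx = np.arange(n)
    rng = np.random.default_rng(seed)
    if mode == "record":
        if k > n:
            raise ValueError("k exceeds the number of records")
        perm = rng.permutation(idx)
        test_folds = [np.sort(f) for f in np.array_split(perm, k)]
    elif mode == "subject":
        if subject_ids is None:
            raise ValueError("subject mode requires subject_ids")
        subjects = np.asarray(subject_ids)
        uniq = np.unique(subjects)
        if k > len(uniq):
            raise ValueError("k exceeds the number of subjects")
        order = rng.permutation(uniq)
        fold_members: list = [[] for _ in range(k)]
        fold_sizes = np.zeros(k, dtype=int)
        for s in order:
            members = idx[subjects == s]
            target = int(np.argmin(fold_sizes))
            fold_members[target].extend(members.tolist())
            fold_sizes[target] += len(members)
        test_folds = [np.sort(np.asarray(f, dtype=int))
                      for f in fold_members]
    else:
        raise ValueError("mode must be 'record' or 'subject'")
    folds = []
    for test in test_folds:
        train = np.setdiff1d(idx, test)
        folds.append((train, test))
    return CVPlan(folds=folds, k=k, mode=mode, seed=seed)


def psnr(reference, estimate, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB against a reference image/signal."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return float("inf")
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    return float(10.0 * np.log10(data_range ** 2 / mse))
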