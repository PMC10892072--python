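"""Confusion-matrix metrics, AUC variants, the 3-class potency table and
applicability-domain flags.

Binary metrics follow the standard confusion-count definitions:

    accuracy            = (TP + TN) / (TP + TN + FP + FN)
    balanced accuracy   = (sensitivity + specificity) / 2
    sensitivity         = TP / (TP + FN)
    specificity         = TN / (FP + TN)
    F1                  = 2 TP / (2 TP + FP + FN)

Two ROC-AUC readings are provided because a majority-vote classifier has
both a hard label and a continuous vote fraction: ``auc_hard`` treats the
hard label itself as the score (a two-point ROC, identically equal to
balanced accuracy) and ``auc_score`` is the Mann-Whitney area computed on
the vote fractions (ties counted 1/2). ``auc_hard`` is the default
reported value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError
from .preprocess import EC15_CAP

CLASS_ORDER = ("NC", "1B", "1A")


@dataclass(frozen=True)
class ConfusionMatrix2:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_pairs(cls, y_true, y_pred, positive) -> "ConfusionMatrix2":
        t = np.asarray(y_true) == positive
        p = np.asarray(y_pred) == positive
        return cls(
            tp=int((t & p).sum()),
            fn=int((t & ~p).sum()),
            fp=int((~t & p).sum()),
            tn=int((~t & ~p).sum()),
        )


@dataclass
class MetricsReport:
    """Binary-stage metrics; a metric with a zero denominator is None."""

    accuracy: float | None
    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc_hard: float | None = None
    auc_score: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(cm: ConfusionMatrix2) -> MetricsReport:
    """Exact metric arithmetic from confusion counts."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.fp + cm.tn)
    bal = None if sens is None or spec is None else (sens + spec) / 2
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        balanced_accuracy=bal,
        sensitivity=sens,
        specificity=spec,
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


def auc_variants(labels, vote_fractions, hard_labels=None) -> tuple[float, float]:
    """(auc_hard, auc_score) for binary labels.

    ``auc_hard`` scores the hard calls (vote fraction thresholded at the
    majority if ``hard_labels`` is not given); for any hard predictor the
    two-point ROC area equals balanced accuracy. ``auc_score`` is the
    Mann-Whitney area on the continuous vote fractions.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC undefined: only one class present")
    frac = np.asarray(vote_fractions, dtype=float)
    hard = np.asarray(hard_labels).astype(int) if hard_labels is not None else (frac >= 0.6).astype(int)
    return float(roc_auc_score(y, hard)), float(roc_auc_score(y, frac))


# ---------------------------------------------------------------------------
# 3-class potency table


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows = predicted class, columns = human class (NC, 1B, 1A)."""

    counts: tuple  # tuple of 3 row-tuples

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValidationError("need a 3x3 matrix of non-negative counts")

    @classmethod
    def from_pairs(cls, y_true, y_pred) -> "ConfusionMatrix3":
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        arr = np.zeros((3, 3), dtype=int)
        for t, p in zip(y_true, y_pred):
            arr[idx[p], idx[t]] += 1
        return cls(tuple(map(tuple, arr)))

    def array(self) -> np.ndarray:
        return np.asarray(self.counts)


def collapse_to_binary(cm3: ConfusionMatrix3) -> ConfusionMatrix2:
    """Merge 1B and 1A into "sensitizer" (positive); NC is negative."""
    a = cm3.array()
    return ConfusionMatrix2(
        tp=int(a[1:, 1:].sum()),
        fn=int(a[0, 1:].sum()),
        fp=int(a[1:, 0].sum()),
        tn=int(a[0, 0]),
    )


def round_half_up(x: float, digits: int = 1) -> float:
    scale = 10**digits
    return math.floor(x * scale + 0.5) / scale


def potency_table(cm3: ConfusionMatrix3) -> dict:
    """Overall accuracy plus per-human-class correct/under/over rates.

    "Under" counts predictions strictly below the true class on the severity
    order NC < 1B < 1A; "over" strictly above. Internal values are exact
    fractions; the ``*_pct`` entries are rounded half-up to one decimal.
    """
    a = cm3.array()
    total = int(a.sum())
    if total == 0 or (a.sum(axis=0) == 0).any():
        raise ValidationError("every human class must have at least one substance")
    overall = a.trace() / total
    per_class = {}
    for j, cls in enumerate(CLASS_ORDER):
        col = a[:, j]
        n = int(col.sum())
        correct = col[j] / n
        under = col[:j].sum() / n
        over = col[j + 1 :].sum() / n
        per_class[cls] = {
            "n": n,
            "correct": correct,
            "underpredicted": under,
            "overpredicted": over,
            "correct_pct": round_half_up(100 * correct),
            "underpredicted_pct": round_half_up(100 * under),
            "overpredicted_pct": round_half_up(100 * over),
        }
    return {
        "overall_accuracy": overall,
        "overall_pct": round_half_up(100 * overall, 1),
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# applicability domain


@dataclass
class DomainRanges:
    """Per-feature training min/max (optionally central-95% bounds)."""

    ranges: dict[str, tuple[float, float]]
    central95: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def fit(cls, train: pd.DataFrame, central: bool = True) -> "DomainRanges":
        ranges, c95 = {}, {}
        for col in train.columns:
            x = train[col].dropna().to_numpy(dtype=float)
            ranges[col] = (float(x.min()), float(x.max()))
            if central:
                lo, hi = np.quantile(x, [0.025, 0.975])
                c95[col] = (float(lo), float(hi))
        return cls(ranges, c95)


def domain_flags(ranges: DomainRanges, features: pd.Series | dict) -> dict[str, str]:
    """Applicability-domain flags for one substance.

    A feature outside its training range is flagged ``out_of_range``; an
    EC1.5 sitting exactly at the censoring cap is flagged as censored (such
    substances have an elevated false-negative risk).
    """
    row = dict(features)
    flags: dict[str, str] = {}
    for f, (lo, hi) in ranges.ranges.items():
        if f not in row or row[f] is None or (isinstance(row[f], float) and math.isnan(row[f])):
            continue
        v = float(row[f])
        if v < lo or v > hi:
            flags[f] = "out_of_range"
    if "EC1.5" in row and row["EC1.5"] is not None and float(row["EC1.5"]) == EC15_CAP:
        flags["EC1.5"] = "censored_at_cap_false_negative_risk"
    return flags
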