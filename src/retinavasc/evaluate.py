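"""Confusion-matrix metrics, ROC AUC and cross-validation averaging.

Positive class throughout is "hypertension". A score at or above the
threshold predicts positive. AUC is the Mann-Whitney probability
P(score+ > score-) + 0.5 * P(tie), computed from midranks.

Metrics with a zero denominator are reported as explicitly undefined
(``None`` value plus an entry in ``MetricsReport.undefined``) rather than
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DataError

POSITIVE = "hypertension"


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float | None
    specificity: float | None
    precision: float | None
    recall: float | None
    auc: float | None
    fold: int | str = 0
    n_images: int = 0
    undefined: list = field(default_factory=list)

    FIELDS = ("accuracy", "specificity", "precision", "recall", "auc")


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN with score >= threshold meaning predicted positive."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if scores.shape != y.shape or scores.size == 0:
        raise DataError("scores and labels must be equal-length and non-empty")
    pred = scores >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts, auc_value: float | None = None,
            fold: int | str = 0) -> MetricsReport:
    """Accuracy, specificity, precision and recall from confusion counts."""
    undefined = []

    def ratio(name, num, den):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    report = MetricsReport(
        accuracy=ratio("accuracy", counts.tp + counts.tn, counts.n),
        specificity=ratio("specificity", counts.tn, counts.tn + counts.fp),
        precision=ratio("precision", counts.tp, counts.tp + counts.fp),
        recall=ratio("recall", counts.tp, counts.tp + counts.fn),
        auc=auc_value,
        fold=fold,
        n_images=counts.n,
    )
    report.undefined = undefined
    return report


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aggregate_cv(fold_reports) -> MetricsReport:
    """Unweighted mean of per-fold reports, as the cross-validation average row."""
    reports = list(fold_reports)
    if not reports:
        raise DataError("no fold reports to aggregate")
    values = {}
    undefined = []
    for name in MetricsReport.FIELDS:
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            undefined.append(name)
            values[name] = None
        else:
            values[name] = float(np.mean(vals))
    out = MetricsReport(
        fold="average", n_images=int(sum(r.n_images for r in reports)), **values
    )
    out.undefined = undefined
    return out


def round_half_up(value: float, digits: int) -> float:
    """Decimal half-up rounding used only at reporting time."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_report(report: MetricsReport) -> dict:
    """Percentages to two decimals, AUC to four — reporting convention."""
    out = {"fold": report.fold, "n": report.n_images}
    for name in ("accuracy", "specificity", "precision", "recall"):
        v = getattr(report, name)
        out[name] = None if v is None else round_half_up(100.0 * v, 2)
    out["auc"] = None if report.auc is None else round_half_up(report.auc, 4)
    return out


def reports_to_frame(reports) -> pd.DataFrame:
    """One row per fold plus the average row, reporting-rounded."""
    rows = [format_report(r) for r in reports]
    rows.append(format_report(aggregate_cv(reports)))
    return pd.DataFrame(rows, columns=["fold", "accuracy", "specificity",
                                       "precision", "recall", "auc", "n"])
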