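"""Binary-classification metrics: SN, SP, ACC, MCC and AUC.

With the positive class = 6mA:

    SN  = TP / (TP + FN)              (sensitivity, recall on 6mA)
    SP  = TN / (FP + TN)              (specificity)
    ACC = (TP + TN) / n
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

AUC is the area under the ROC curve, computed here as the normalized
rank-sum (Mann–Whitney) statistic with half credit for ties — identical to
the trapezoidal area under the tie-aware ROC curve.

A metric whose denominator vanishes is *undefined*, reported as ``None``
(never silently zero — a silent zero would corrupt greedy model searches).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .errors import ContractError, UndefinedMetricError
from .sequence_io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2×2 tally for one evaluation (positive class = 1)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two equal-length binary vectors."""
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ContractError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if v.size and not np.isin(v, (0, 1)).all():
            raise ContractError(f"{name} contains non-binary values")
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


@dataclass(frozen=True)
class LabelMetrics:
    """Threshold-dependent metrics; ``None`` marks an undefined value."""

    SN: Optional[float]
    SP: Optional[float]
    ACC: float
    MCC: Optional[float]


def compute_metrics(counts: ConfusionCounts) -> LabelMetrics:
    """SN, SP, ACC, MCC from a confusion table.

    Raises :class:`UndefinedMetricError` on an empty table; individual
    metrics with zero denominators come back as ``None``.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise UndefinedMetricError("no samples: every metric is undefined")
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (fp + tn) if (fp + tn) > 0 else None
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return LabelMetrics(SN=sn, SP=sp, ACC=acc, MCC=mcc)


def roc_auc(y_true, scores) -> tuple[float, list[tuple[float, float, float]]]:
    """AUC plus the ROC points, in threshold order.

    AUC is the fraction of (positive, negative) pairs ranked correctly by
    ``scores``, counting ties as 1/2.  ROC points are (fpr, tpr, threshold).
    """
    yt = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ContractError(f"shape mismatch: {yt.shape} vs {s.shape}")
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    ranks = rankdata(s)  # average ranks give ties half credit
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresh = roc_curve(yt, s)
    points = list(zip(fpr.tolist(), tpr.tolist(), thresh.tolist()))
    return float(auc), points


@dataclass(frozen=True)
class MetricsReport:
    """Counts + SN/SP/ACC/MCC at one threshold, plus threshold-free AUC."""

    counts: ConfusionCounts
    SN: Optional[float]
    SP: Optional[float]
    ACC: float
    MCC: Optional[float]
    AUC: Optional[float]
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "TP": self.counts.TP,
            "TN": self.counts.TN,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "SN": self.SN,
            "SP": self.SP,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "threshold": self.threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def report_from_scores(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Build a full report from true labels and positive-class scores."""
    yt = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    counts = confusion_counts(yt, (s >= threshold).astype(np.int64))
    label_metrics = compute_metrics(counts)
    try:
        auc, _ = roc_auc(yt, s)
    except UndefinedMetricError:
        auc = None
    return MetricsReport(
        counts=counts,
        SN=label_metrics.SN,
        SP=label_metrics.SP,
        ACC=label_metrics.ACC,
        MCC=label_metrics.MCC,
        AUC=auc,
        threshold=threshold,
    )


def evaluate(model, dataset: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
    """Score a fitted stacking model against a labeled dataset."""
    from .stacking import predict_proba

    scores = predict_proba(model, dataset)
    return report_from_scores(dataset.labels, scores, threshold=threshold)


def roc_points_to_csv(points, path: str | Path) -> None:
    """Write ROC points as a CSV with columns fpr, tpr, threshold."""
    with open(path, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for fpr, tpr, thresh in points:
            fh.write(f"{fpr},{tpr},{thresh}\n")
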