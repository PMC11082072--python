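"""Confusion-matrix metrics, ROC/AUC, and model evaluation.

Accuracy = (TN+TP)/(TN+TP+FN+FP), Sensitivity = TP/(TP+FN),
Specificity = TN/(TN+FP), and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Ratios with a zero denominator return 0 (safe convention). AUC is the
tie-aware Mann–Whitney rank statistic, which equals trapezoidal
integration of the ROC curve over all thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .model import DualModel, forward_pass
from .records import PeptideDataset
from .tokenization import tokenize_dataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: Optional[float] = None
    counts: Optional[ConfusionCounts] = None
    classifier_id: Optional[int] = None

    def report_fields(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": float("nan") if self.auc is None else self.auc,
        }

    def to_dict(self) -> dict:
        d = self.report_fields()
        if self.counts is not None:
            d.update(tp=self.counts.tp, tn=self.counts.tn,
                     fp=self.counts.fp, fn=self.counts.fn)
        if self.classifier_id is not None:
            d["classifier_id"] = self.classifier_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        counts = None
        if "tp" in d:
            counts = ConfusionCounts(tp=d["tp"], tn=d["tn"], fp=d["fp"], fn=d["fn"])
        auc = d.get("auc")
        if auc is not None and math.isnan(auc):
            auc = None
        return cls(accuracy=d["accuracy"], sensitivity=d["sensitivity"],
                   specificity=d["specificity"], mcc=d["mcc"], auc=auc,
                   counts=counts, classifier_id=d.get("classifier_id"))


def confusion_counts(labels, predictions) -> ConfusionCounts:
    """Count TP/TN/FP/FN with class 1 (ACP) as the positive class."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs "
            f"{predictions.shape} predictions"
        )
    if labels.size < 1:
        raise ValueError("need at least one sample")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the four confusion-matrix formulas (AUC left unset)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = _safe_ratio(tn + tp, counts.total)
    sensitivity = _safe_ratio(tp, tp + fn)
    specificity = _safe_ratio(tn, tn + fp)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_ratio(float(tp) * tn - float(fp) * fn, denom)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, mcc=mcc, counts=counts)


def roc_auc(labels, scores) -> float:
    """AUC via the Mann–Whitney rank statistic; ties count 0.5."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve_points(labels, scores) -> np.ndarray:
    """(fpr, tpr) pairs at every distinct threshold, for plotting/export."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = max(int(np.sum(labels == 1)), 1)
    n_neg = max(int(np.sum(labels == 0)), 1)
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    distinct = np.r_[np.where(np.diff(scores))[0], labels.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr])


def predict_scores(model: DualModel, dataset: PeptideDataset,
                   classifier: int = 1) -> np.ndarray:
    """Class-1 probabilities from the chosen head, dropout disabled."""
    if classifier not in (1, 2):
        raise ValueError(f"classifier must be 1 or 2, got {classifier}")
    model.set_training(False)
    max_len = model.config.max_len
    batch_1 = tokenize_dataset(dataset.sequences, model.vocab_1, max_len)
    batch_2 = tokenize_dataset(dataset.sequences, model.vocab_2, max_len)
    out = forward_pass(model, batch_1, batch_2)
    probs = out.probs_1 if classifier == 1 else out.probs_2
    return probs.data[:, 1].copy()


def evaluate_model(model: DualModel, dataset: PeptideDataset,
                   classifier: int = 1, threshold: float = 0.5) -> MetricsReport:
    """Metrics for one classification head on a labeled dataset."""
    if not dataset.labeled():
        raise ValueError("evaluate_model requires a fully labeled dataset")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    labels = np.asarray(dataset.labels, dtype=np.int64)
    scores = predict_scores(model, dataset, classifier)
    predictions = (scores >= threshold).astype(np.int64)
    report = compute_metrics(confusion_counts(labels, predictions))
    if len(set(labels.tolist())) == 2:
        report.auc = roc_auc(labels, scores)
    report.classifier_id = classifier
    return report
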