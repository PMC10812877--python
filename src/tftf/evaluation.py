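"""Metrics: confusion counts, ANSR accuracy, threshold sweeps, correlation.

All hard labels derive from the Confidence Score x1 - x2 at a threshold
(default 0). ANSR accuracy is the fraction of the ANSR cohort predicted
negative, which equals 1 minus the false-positive rate on that cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_curve


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    ansr_accuracy: float | None = None
    auprc: float | None = None
    auroc: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _confidences(preds) -> np.ndarray:
    if len(preds) and hasattr(preds[0], "confidence"):
        return np.array([p.confidence for p in preds])
    return np.asarray(preds, dtype=float)


def confusion(preds, labels, threshold: float = 0.0) -> MetricsReport:
    """Counts and P/R/F1 at a threshold.

    ``preds`` is a list of Prediction objects or an array of Confidence
    Scores; ``labels`` is boolean (True = positive). Undefined precision or
    recall (empty denominator) is reported as 0 with a flag.
    """
    conf = _confidences(preds)
    labels = np.asarray(labels, dtype=bool)
    if conf.size == 0:
        raise ValueError("empty input")
    if conf.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    called = conf > threshold
    tp = int((called & labels).sum())
    fp = int((called & ~labels).sum())
    fn = int((~called & labels).sum())
    tn = int((~called & ~labels).sum())
    p_def, r_def = tp + fp > 0, tp + fn > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(tp, fp, tn, fn, precision, recall, f1, p_def, r_def)


def ansr_accuracy(preds, threshold: float = 0.0) -> float | None:
    """Fraction of ANSR samples predicted negative (n/N); None when empty."""
    conf = _confidences(preds)
    if conf.size == 0:
        return None
    return float((conf <= threshold).mean())


@dataclass
class CurveSet:
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auprc: float
    auroc: float

    def to_frames(self):
        import pandas as pd

        pr = pd.DataFrame({"recall": self.recall, "precision": self.precision})
        roc = pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})
        return pr, roc


def sweep_curves(confidences, labels) -> CurveSet:
    """PR and ROC curves over all distinct confidence thresholds.

    Areas are trapezoidal; the PR curve includes the (recall 0, precision 1)
    endpoint. Raises on one-class input.
    """
    conf = _confidences(confidences)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to sweep thresholds")
    precision, recall, pr_thr = precision_recall_curve(labels, conf)
    fpr, tpr, roc_thr = roc_curve(labels, conf)
    # precision_recall_curve returns recall decreasing, ending at (0, 1)
    auprc = float(auc(recall[::-1], precision[::-1]))
    auroc = float(auc(fpr, tpr))
    return CurveSet(precision, recall, pr_thr, fpr, tpr, roc_thr, auprc, auroc)


def confidence_vs_enrichment(confidences, enrichments) -> float | None:
    """Pearson correlation between Confidence Score and ChIP enrichment.

    Returns None when either vector has zero variance; requires >= 3 pairs.
    """
    conf = _confidences(confidences)
    enr = np.asarray(enrichments, dtype=float)
    if conf.size != enr.size:
        raise ValueError("paired vectors differ in length")
    if conf.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(conf) == 0 or np.std(enr) == 0:
        return None
    return float(stats.pearsonr(conf, enr).statistic)


def full_report(
    test_conf, test_labels, ansr_conf=None, threshold: float = 0.0
) -> MetricsReport:
    """Confusion report plus ANSR accuracy and curve areas when computable."""
    report = confusion(test_conf, test_labels, threshold)
    if ansr_conf is not None and len(ansr_conf):
        report.ansr_accuracy = ansr_accuracy(ansr_conf, threshold)
    labels = np.asarray(test_labels, dtype=bool)
    if labels.any() and not labels.all():
        curves = sweep_curves(test_conf, labels)
        report.auprc, report.auroc = curves.auprc, curves.auroc
    return report
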