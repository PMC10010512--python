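"""Classification metrics: AUROC, specificity-constrained thresholding, confusion metrics.

AUROC follows the Mann–Whitney convention: the probability a random case scores
above a random control, with ties counted one half. Thresholds for the derived
confusion-matrix metrics are chosen to maximize F1 subject to a minimum
specificity (default 0.85), the operating rule of a screening tool that must
keep false positives low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class MetricReport:
    auroc: float
    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    feasible: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be coded {0, 1} with cases = 1")
    return labels


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: fraction of (case, control) pairs ranked correctly."""
    labels = _check_classes(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(scores, labels, threshold: float,
                      auroc_value: float | None = None) -> MetricReport:
    """Standard 2×2 metrics with positive = case, predicted positive = score > threshold."""
    labels = _check_classes(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(labels)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    if auroc_value is None:
        auroc_value = auroc(scores, labels)
    return MetricReport(auroc_value, float(threshold), sens, spec, prec, acc, f1)


def select_threshold(scores, labels, min_specificity: float = 0.85
                     ) -> tuple[float, MetricReport]:
    """Threshold maximizing F1 subject to specificity ≥ ``min_specificity``.

    Candidates are the midpoints between adjacent sorted unique scores plus ±∞;
    ties in F1 break toward higher specificity, then higher threshold. A
    feasible candidate always exists because +∞ yields specificity 1.
    """
    labels = _check_classes(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = [-np.inf, np.inf]
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    auc = auroc(scores, labels)
    best = None
    best_key = None
    for th in candidates:
        rep = confusion_metrics(scores, labels, th, auroc_value=auc)
        if rep.specificity < min_specificity:
            continue
        key = (rep.f1, rep.specificity, th)
        if best_key is None or key > best_key:
            best, best_key = rep, key
    assert best is not None  # +inf always feasible
    best.feasible = True
    return best.threshold, best
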