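"""Multi-class metrics, inference-time ensembling, seed aggregation, and the
leave-one-video-out planning helper."""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (
    average_precision_score, confusion_matrix as _sk_confusion,
    f1_score, precision_score, recall_score, roc_auc_score,
)

__all__ = [
    "MetricReport", "evaluate", "ensemble_predict", "aggregate_seeds",
    "loocv_plan",
]

_SCALARS = ("accuracy", "micro_ap", "macro_precision", "recall", "f1",
            "micro_auc", "macro_auc")


@dataclass
class MetricReport:
    accuracy: float
    micro_ap: float
    macro_precision: float
    recall: float            # macro-averaged
    f1: float                # macro-averaged
    micro_auc: float
    macro_auc: float
    confusion: np.ndarray

    def scalars(self):
        d = asdict(self)
        return {k: d[k] for k in _SCALARS}


def evaluate(probabilities, labels, num_classes=None) -> MetricReport:
    """Score predicted class distributions against integer labels.

    Accuracy uses the argmax decision (ties toward the lowest class index,
    numpy convention); AP is micro-averaged over pooled one-vs-rest
    decisions; precision/recall/F1 are macro-averaged; AUC is one-vs-rest in
    both micro and macro form.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or len(probs) != len(labels):
        raise ValueError("probabilities must be N x K matching N labels")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-5:
        raise ValueError("probability rows must sum to 1")
    k = probs.shape[1] if num_classes is None else num_classes
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label outside [0, K)")
    preds = probs.argmax(axis=1)
    onehot = np.eye(k)[labels]
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least two classes present to evaluate")
    # restrict rank metrics to classes with support to keep them defined
    micro_ap = average_precision_score(onehot[:, present], probs[:, present],
                                       average="micro")
    micro_auc = roc_auc_score(onehot[:, present].ravel(), probs[:, present].ravel())
    macro_auc = float(np.mean([roc_auc_score(onehot[:, c], probs[:, c])
                               for c in present]))
    return MetricReport(
        accuracy=float((preds == labels).mean()),
        micro_ap=float(micro_ap),
        macro_precision=float(precision_score(labels, preds, average="macro",
                                              labels=np.arange(k), zero_division=0)),
        recall=float(recall_score(labels, preds, average="macro",
                                  labels=np.arange(k), zero_division=0)),
        f1=float(f1_score(labels, preds, average="macro",
                          labels=np.arange(k), zero_division=0)),
        micro_auc=float(micro_auc),
        macro_auc=macro_auc,
        confusion=_sk_confusion(labels, preds, labels=np.arange(k)),
    )


def ensemble_predict(prob_sets) -> np.ndarray:
    """Average predicted distributions across models at inference time."""
    arrays = [np.asarray(p, dtype=np.float64) for p in prob_sets]
    if not arrays:
        raise ValueError("need at least one probability set")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("probability sets must share one shape")
    return np.mean(arrays, axis=0)


def aggregate_seeds(reports) -> tuple[dict, dict]:
    """Per-metric mean and population standard deviation across seed runs."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    keys = _SCALARS
    mean = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    std = {k: float(np.std([getattr(r, k) for r in reports])) for k in keys}
    return mean, std


def loocv_plan(videos) -> list[tuple[list, list]]:
    """One (train, test) fold per video; test sets partition the video list."""
    videos = list(videos)
    if len(videos) != len(set(videos)):
        raise ValueError("duplicate video ids")
    if len(videos) < 2:
        raise ValueError("need at least two videos")
    return [([v for v in videos if v != held], [held]) for held in videos]
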