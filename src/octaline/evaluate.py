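"""Per-A-line evaluation: confusion matrix, accuracy / sensitivity /
specificity (lipid is the positive class), and prediction throughput.
"""

from __future__ import annotations

import platform
import time
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with lipid as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float | None  # None when tp+fn == 0
    specificity: float | None  # None when tn+fp == 0
    n_alines: int
    per_bscan: dict = field(default_factory=dict)


def confusion_from_predictions(pred, truth) -> ConfusionMatrix:
    pred = np.asarray(pred).astype(int).ravel()
    truth = np.asarray(truth).astype(int).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    bad = set(np.unique(pred)) | set(np.unique(truth))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be binary, found {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def classification_metrics(cm: ConfusionMatrix) -> EvalReport:
    if cm.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn == 0:
        warnings.warn("no positive (lipid) A-lines: sensitivity undefined")
        sensitivity = None
    else:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    if cm.tn + cm.fp == 0:
        warnings.warn("no negative (other) A-lines: specificity undefined")
        specificity = None
    else:
        specificity = cm.tn / (cm.tn + cm.fp)
    return EvalReport(cm, accuracy, sensitivity, specificity, cm.total)


def evaluate_predictions(pred, truth, bscan_ids=None) -> EvalReport:
    """Pooled report, optionally with a per-B-scan breakdown."""
    report = classification_metrics(confusion_from_predictions(pred, truth))
    if bscan_ids is not None:
        bscan_ids = np.asarray(bscan_ids)
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        for bid in np.unique(bscan_ids):
            m = bscan_ids == bid
            report.per_bscan[int(bid)] = confusion_from_predictions(pred[m], truth[m])
    return report


def throughput_benchmark(clf, batches, repeats: int = 3) -> dict:
    """Median prediction-only rate in B-scans per second.

    Times argmax inference over the supplied preprocessed batches
    (preprocessing excluded).  Purely observational: the number is
    hardware-dependent and reported alongside a hardware descriptor.
    """
    if not batches:
        raise ValueError("need at least one preprocessed B-scan batch")
    rates = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        for batch in batches:
            clf.predict(batch)
        dt = time.perf_counter() - t0
        rates.append(len(batches) / dt)
    return {
        "bscans_per_s_median": float(np.median(rates)),
        "bscans_per_s_per_repeat": [float(r) for r in rates],
        "n_bscans": len(batches),
        "repeats": repeats,
        "hardware": f"{platform.processor() or platform.machine()} / {platform.system()}",
    }
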