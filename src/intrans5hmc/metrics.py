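"""Confusion counts, the nine-metric evaluation report, and stratified CV folds.

The report carries sensitivity (SN), specificity (SP), accuracy (ACC),
balanced accuracy (BACC = (SN+SP)/2), precision (PREC), F1 (harmonic mean of
PREC and SN), Matthews correlation (MCC), ROC AUC and area under the
precision-recall curve (AUPR).  A probability equal to the threshold counts
as a positive prediction.  Metrics whose denominator is zero are reported
as 0 and flagged, so batch experiments never abort mid-table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("SN", "SP", "ACC", "BACC", "PREC", "F1", "MCC", "AUC", "AUPR")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    SN: float
    SP: float
    ACC: float
    BACC: float
    PREC: float
    F1: float
    MCC: float
    AUC: float
    AUPR: float
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        if self.counts is not None:
            d["counts"] = asdict(self.counts)
        if self.undefined:
            d["undefined"] = list(self.undefined)
        return d

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])


def confusion(y_true: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; prob >= threshold predicts positive."""
    y_true = np.asarray(y_true).astype(int)
    probs = np.asarray(probs, dtype=float)
    if y_true.shape != probs.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {probs.shape}")
    pred = probs >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Threshold metrics from raw counts (no ranking metrics)."""
    undefined: list[str] = []
    sn = _safe_div(c.TP, c.TP + c.FN, "SN", undefined)
    sp = _safe_div(c.TN, c.TN + c.FP, "SP", undefined)
    acc = _safe_div(c.TP + c.TN, c.total, "ACC", undefined)
    prec = _safe_div(c.TP, c.TP + c.FP, "PREC", undefined)
    f1 = _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1", undefined)
    mcc_den = math.sqrt(float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC", undefined)
    return {"SN": sn, "SP": sp, "ACC": acc, "BACC": (sn + sp) / 2.0,
            "PREC": prec, "F1": f1, "MCC": mcc, "_undefined": undefined}


def compute_metrics(y_true: np.ndarray, probs: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """Full nine-metric report from labels and predicted probabilities.

    AUC uses midrank handling of ties (a tied positive-negative pair counts
    one half); AUPR is the step-interpolated area under the
    precision-recall curve.  With a single-class truth both are flagged
    undefined and reported as 0.
    """
    y_true = np.asarray(y_true).astype(int)
    probs = np.asarray(probs, dtype=float)
    c = confusion(y_true, probs, threshold)
    base = metrics_from_counts(c)
    undefined = base.pop("_undefined")
    if len(np.unique(y_true)) < 2:
        auc = aupr = 0.0
        undefined.extend(["AUC", "AUPR"])
    else:
        auc = float(roc_auc_score(y_true, probs))
        aupr = float(average_precision_score(y_true, probs))
    return MetricReport(**base, AUC=auc, AUPR=aupr, counts=c,
                        undefined=tuple(undefined))


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold index pairs (train_idx, test_idx).

    Folds are disjoint, cover all samples, and per-class counts per fold
    differ by at most one.
    """
    labels = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]
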