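"""ROC analysis and threshold calibration for the signature score.

Positives are responders and a higher score predicts response.  AUC is
computed as the tie-corrected Mann-Whitney probability that a random
responder outscores a random poor responder.  The operating threshold
is calibrated under the assumption of equally frequent type I and type
II errors: among candidate thresholds (midpoints between adjacent
distinct scores, plus one beyond each extreme) pick the one minimizing
|FPR - FNR|, breaking ties by maximal Matthews correlation coefficient
and then by the lowest threshold (which favors sensitivity).
Classification rule: score strictly greater than threshold = predicted
responder.

Note the calibrated threshold is a property of the scored cohort; on a
different dataset the same procedure yields a different cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortAnnotation
from .errors import DegenerateDataError
from .signature import ScoreSet

__all__ = [
    "ROCResult",
    "ThresholdReport",
    "roc_auc",
    "equal_error_threshold",
    "confusion_metrics",
    "candidate_thresholds",
    "plot_roc",
]


@dataclass
class ROCResult:
    auc: float
    #: (threshold, FPR, TPR) triples, from the most permissive cut upwards
    points: list[tuple[float, float, float]] = field(repr=False)

    def as_dict(self) -> dict:
        return {"auc": self.auc, "points": [list(p) for p in self.points]}


@dataclass
class ThresholdReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "confusion_matrix": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }


def _as_arrays(
    scores: Union[ScoreSet, pd.Series, Sequence[float]],
    labels: Union[CohortAnnotation, pd.Series, Sequence[bool]],
) -> tuple[np.ndarray, np.ndarray]:
    """Coerce (scores, labels) to aligned float/bool arrays; labels True = responder."""
    if isinstance(scores, ScoreSet):
        scores = scores.scores
    if isinstance(labels, CohortAnnotation):
        labels = labels.is_responder
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        labels = labels.reindex(scores.index)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise DegenerateDataError(f"samples without labels: {missing}")
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise DegenerateDataError("scores and labels have different lengths")
    if y.all() or not y.any():
        raise DegenerateDataError("both classes must be present")
    if not np.isfinite(s).all():
        raise DegenerateDataError("non-finite score")
    return s, y


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus one candidate
    beyond each extreme (classify-all and classify-none)."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def _confusion_at(scores: np.ndarray, y: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = scores > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return tp, fp, tn, fn


def roc_auc(
    scores: Union[ScoreSet, pd.Series, Sequence[float]],
    labels: Union[CohortAnnotation, pd.Series, Sequence[bool]],
) -> ROCResult:
    """ROC curve and tie-corrected AUC.

    AUC = (#concordant pairs + 0.5 #tied pairs) / (#pos * #neg),
    computed via mid-ranks; identical to the Mann-Whitney U statistic
    scaled to [0, 1].
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    points = []
    for t in candidate_thresholds(s):
        tp, fp, tn, fn = _confusion_at(s, y, t)
        points.append((float(t), fp / n_neg, tp / n_pos))
    return ROCResult(auc=float(auc), points=points)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Sensitivity, specificity and MCC from a 2x2 confusion matrix.

    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    factor under the root is zero the MCC is defined as 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise DegenerateDataError(f"{name} must be a non-negative integer, got {v}")
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateDataError("confusion matrix has an empty class")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "mcc": mcc,
    }


def equal_error_threshold(
    scores: Union[ScoreSet, pd.Series, Sequence[float]],
    labels: Union[CohortAnnotation, pd.Series, Sequence[bool]],
    policy: str = "rates",
) -> ThresholdReport:
    """Calibrate the score threshold for equally frequent type I/II errors.

    ``policy="rates"`` balances FPR against FNR (default); ``"counts"``
    balances the absolute numbers FP against FN (equivalent up to
    group-size scaling).  Tie-break: maximal MCC, then lowest threshold.
    """
    if policy not in ("rates", "counts"):
        raise DegenerateDataError(f"unknown threshold policy {policy!r}")
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best_key, best_confusion, best_threshold = None, None, None
    for t in candidate_thresholds(s):
        tp, fp, tn, fn = _confusion_at(s, y, t)
        if policy == "rates":
            gap = abs(fp / n_neg - fn / n_pos)
        else:
            gap = abs(fp - fn)
        mcc = confusion_metrics(tp, fp, tn, fn)["mcc"]
        key = (gap, -mcc, t)
        if best_key is None or key < best_key:
            best_key, best_confusion, best_threshold = key, (tp, fp, tn, fn), t
    tp, fp, tn, fn = best_confusion
    threshold = best_threshold
    metrics = confusion_metrics(tp, fp, tn, fn)
    return ThresholdReport(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        mcc=metrics["mcc"],
    )


def plot_roc(roc: ROCResult, path, title: str = "ROC curve"):
    """Write a simple ROC plot to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[1] for p in roc.points][::-1]
    tpr = [p[2] for p in roc.points][::-1]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, marker="o", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"{title} (AUC = {roc.auc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
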