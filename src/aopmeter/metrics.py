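"""Evaluation metrics: classification rates, Dice, endpoint distances,
pubic-symphysis axis angle (APT), |ΔAoP| and Bland–Altman agreement.

Degenerate cases (zero denominators, empty classes) are reported as NaN so a
batch report can flag them instead of crashing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts", "AgreementStats",
    "classification_metrics", "dice_score", "endpoint_distance",
    "apt", "delta_aop", "agreement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_labels(cls, pred, true) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(bool)
        true = np.asarray(true).astype(bool)
        return cls(tp=int((pred & true).sum()), fp=int((pred & ~true).sum()),
                   fn=int((~pred & true).sum()), tn=int((~pred & ~true).sum()))


def _ratio(num, den) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, sensitivity, specificity from confusion counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return {
        "accuracy": _ratio(tp + tn, tp + fp + fn + tn),
        "precision": _ratio(tp, tp + fp),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, fp + tn),
    }


def dice_score(pred_mask, true_mask, class_set=(1, 2)) -> dict:
    """Per-class and pooled-foreground Dice (2TP/(2TP+FP+FN)) + pixel accuracy.

    The pooled score micro-averages TP/FP/FN over the foreground classes.
    An empty class in both masks yields NaN for that class.
    """
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    out = {}
    pooled = np.zeros(3)  # tp, fp, fn
    for c in class_set:
        p = pred == c
        t = true == c
        tp = int((p & t).sum())
        fp = int((p & ~t).sum())
        fn = int((~p & t).sum())
        out[f"dice_{c}"] = _ratio(2 * tp, 2 * tp + fp + fn)
        pooled += (tp, fp, fn)
    out["dice_all"] = _ratio(2 * pooled[0], 2 * pooled[0] + pooled[1] + pooled[2])
    out["pixel_accuracy"] = float((pred == true).mean())
    return out


def endpoint_distance(pred_pt, true_pt, pixel_spacing_mm: float = 1.0) -> float:
    """Euclidean endpoint error in millimetres."""
    d = np.asarray(pred_pt, float) - np.asarray(true_pt, float)
    return float(np.hypot(*d) * pixel_spacing_mm)


def apt(pred_left, pred_right, true_left, true_right) -> float:
    """Angle in [0, 90] degrees between the predicted and true PS axis lines.

    The lines are treated as undirected: the reported angle is
    ``min(theta, 180 - theta)``.
    """
    u = np.asarray(pred_right, float) - np.asarray(pred_left, float)
    v = np.asarray(true_right, float) - np.asarray(true_left, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident endpoints define no line")
    cosang = np.clip(abs(np.dot(u, v)) / (nu * nv), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def delta_aop(aop_pred: float, aop_true: float) -> float:
    """|AoP_pred - AoP_true| in degrees."""
    return abs(float(aop_pred) - float(aop_true))


@dataclass(frozen=True)
class AgreementStats:
    """Pearson/regression/Bland–Altman agreement between paired angle sets."""

    pearson_r: float
    slope: float
    intercept: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def agreement(pred_angles, true_angles) -> AgreementStats:
    """Agreement statistics of predicted vs reference angles.

    Differences are ``pred - true``; limits of agreement are
    ``mean +/- 1.96 * SD`` with the sample (n-1) standard deviation.
    """
    pred = np.asarray(pred_angles, float)
    true = np.asarray(true_angles, float)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("need >= 3 paired angles")
    if np.std(pred) == 0 or np.std(true) == 0:
        r, slope, intercept = float("nan"), float("nan"), float("nan")
        if np.allclose(pred, true):
            r = 1.0
    else:
        r = float(stats.pearsonr(pred, true).statistic)
        reg = stats.linregress(true, pred)
        slope, intercept = float(reg.slope), float(reg.intercept)
    diffs = pred - true
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)) * 100.0)
    return AgreementStats(pearson_r=r, slope=slope, intercept=intercept,
                          mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
                          pct_within_loa=within, n=len(pred))
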