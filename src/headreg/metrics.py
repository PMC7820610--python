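"""Registration overlap/structural metrics and classification metrics.

Overlap metrics operate on binary foreground masks x (reference) and y
(prediction):

    DSC = 2|x n y| / (|x| + |y|)        JSC = |x n y| / |x u y|
    R_p = |x n y| / |y|                 R_s = |x n y| / |x|
    CMS = 2 R_p R_s / (R_p + R_s)

For binary masks CMS is algebraically identical to DSC, and
DSC = 2 JSC / (1 + JSC).  SSIM is evaluated globally (single window) from
the means, variances and cross-covariance of the gray volumes with the
standard regularization constants C1 = (0.01 L)^2, C2 = (0.03 L)^2 for
declared intensity range L.

Classification metrics are computed exactly from confusion counts;
0/0 ratios are reported as NaN with the metric name flagged as undefined
rather than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symmetry import intensity_thresholds
from .volume import Volume


@dataclass(frozen=True)
class MetricReport:
    dsc: float
    jsc: float
    r_precision: float
    r_sensitivity: float
    cms: float
    ssim: float

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "jsc": self.jsc,
            "r_precision": self.r_precision,
            "r_sensitivity": self.r_sensitivity,
            "cms": self.cms,
            "ssim": self.ssim,
        }


@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    g_mean: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f_measure": self.f_measure, "g_mean": self.g_mean,
            "undefined": sorted(self.undefined),
        }


def binarize_for_overlap(v: Volume) -> np.ndarray:
    """Foreground mask from Otsu two-level thresholding (lowest class = background)."""
    thr1, _ = intensity_thresholds(v)
    mask = v.voxels > thr1
    if not mask.any():
        raise ValueError("empty foreground mask")
    return mask


def overlap_metrics(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """(DSC, JSC, R_p, R_s, CMS) of two same-shape binary masks.

    Disjoint masks give all zeros (CMS defined as 0 when R_p = R_s = 0).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 or ny == 0:
        raise ValueError("empty mask")
    inter = int(np.logical_and(x, y).sum())
    union = nx + ny - inter
    dsc = 2.0 * inter / (nx + ny)
    jsc = inter / union
    r_p = inter / ny
    r_s = inter / nx
    cms = 0.0 if (r_p + r_s) == 0 else 2.0 * r_p * r_s / (r_p + r_s)
    return dsc, jsc, r_p, r_s, cms


def ssim_global(
    x: Volume | np.ndarray,
    y: Volume | np.ndarray,
    data_range: float | None = None,
    C1: float | None = None,
    C2: float | None = None,
) -> float:
    """Single-window SSIM from global image moments."""
    xv = np.asarray(x.voxels if isinstance(x, Volume) else x, dtype=float).ravel()
    yv = np.asarray(y.voxels if isinstance(y, Volume) else y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError("volumes must share a grid")
    if data_range is None:
        data_range = float(max(xv.max(), yv.max()) - min(xv.min(), yv.min()))
        if data_range == 0:
            data_range = 1.0
    if C1 is None:
        C1 = (0.01 * data_range) ** 2
    if C2 is None:
        C2 = (0.03 * data_range) ** 2
    mx, my = xv.mean(), yv.mean()
    vx = xv.var()
    vy = yv.var()
    cov = np.mean((xv - mx) * (yv - my))
    return float(((2 * mx * my + C1) * (2 * cov + C2)) / ((mx**2 + my**2 + C1) * (vx + vy + C2)))


def classification_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassificationReport:
    """Exact confusion-matrix metrics with explicit undefined-ratio flags."""
    counts = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
    if any(c < 0 for c in counts.values()):
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if np.isnan(sensitivity) or np.isnan(precision) or (precision + sensitivity) == 0:
        undefined.add("f_measure")
        f_measure = float("nan")
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    if np.isnan(sensitivity) or np.isnan(specificity):
        undefined.add("g_mean")
        g_mean = float("nan")
    else:
        g_mean = float(np.sqrt(sensitivity * specificity))
    return ClassificationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, f_measure=f_measure, g_mean=g_mean,
        undefined=frozenset(undefined),
    )


def evaluate_registration(
    fixed: Volume, registered: Volume, ground_truth_registered: Volume
) -> MetricReport:
    """Score a predicted registration against the ground-truth registration.

    Overlap metrics compare the Otsu-binarized ground-truth (reference x)
    and predicted (y) registered volumes; SSIM compares the gray volumes.
    """
    if registered.dims != ground_truth_registered.dims:
        raise ValueError("registered and ground-truth volumes must share a grid")
    x = binarize_for_overlap(ground_truth_registered)
    y = binarize_for_overlap(registered)
    dsc, jsc, r_p, r_s, cms = overlap_metrics(x, y)
    ssim = ssim_global(ground_truth_registered, registered)
    return MetricReport(dsc=dsc, jsc=jsc, r_precision=r_p, r_sensitivity=r_s, cms=cms, ssim=ssim)
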