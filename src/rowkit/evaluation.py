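"""Accuracy metrics for extracted crop rows and plant detections.

Row metrics follow the navigation-oriented convention: the angular
deviation theta between a ground-truth centerline (slope m1) and a fitted
one (slope m2) is the inter-line angle

    theta = arctan(|m1 - m2| / |1 + m1 m2|)   (degrees, 90 at the singularity)

and an extraction is valid when theta is below a threshold (5 degrees by
default).  The center deviation delta is the mean absolute horizontal
offset between the two lines at sampled vertical positions.  Aggregation
averages per image first, then across images, matching the double-sum
definitions; the validity rate P is valid rows over total ground-truth rows.

Detection quality uses the usual precision / recall / AP at IoU 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EvalConfig",
    "RowMatch",
    "EvalAggregates",
    "PRResult",
    "angular_error",
    "center_deviation",
    "evaluate_image",
    "aggregate",
    "detection_pr",
]


@dataclass(frozen=True)
class EvalConfig:
    """validity_threshold in degrees; y_samples are the vertical positions
    (evaluation-space units) where center deviation is measured."""

    validity_threshold: float = 5.0
    y_samples: tuple[float, ...] = (120.0, 240.0, 360.0)

    def __post_init__(self) -> None:
        if not (self.validity_threshold > 0):
            raise ValueError("validity_threshold must be positive")
        if len(self.y_samples) == 0:
            raise ValueError("y_samples must be nonempty")

    @classmethod
    def for_image_height(cls, height: float, validity_threshold: float = 5.0) -> "EvalConfig":
        """Sample at 1/4, 1/2 and 3/4 of the image height."""
        return cls(
            validity_threshold=validity_threshold,
            y_samples=(0.25 * height, 0.5 * height, 0.75 * height),
        )


@dataclass(frozen=True)
class RowMatch:
    """One ground-truth row paired (or not) with a fitted row."""

    gt_slope: float
    gt_intercept: float
    fitted_slope: float | None
    fitted_intercept: float | None
    theta: float
    delta: float
    valid: bool

    @property
    def matched(self) -> bool:
        return self.fitted_slope is not None


@dataclass(frozen=True)
class EvalAggregates:
    mean_theta: float
    sd_theta: float
    mean_delta: float
    sd_delta: float
    validity_rate: float
    mean_time_ms: float
    fps: float
    n_images: int
    n_rows: int


def angular_error(m1: float, m2: float) -> float:
    """Inter-line angle in degrees between lines of slope m1 and m2.

    Clamped to [0, 90]; returns 90 when the lines are perpendicular
    (vanishing denominator |1 + m1 m2|).
    """
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValueError("slopes must be finite")
    denom = abs(1.0 + m1 * m2)
    if denom < 1e-12:
        return 90.0
    theta = math.degrees(math.atan(abs(m1 - m2) / denom))
    return min(max(theta, 0.0), 90.0)


def center_deviation(
    gt: tuple[float, float],
    fit: tuple[float, float],
    y_samples: Sequence[float],
) -> float:
    """Mean |x_gt - x_fit| over the sampled vertical positions, both lines
    given as (slope, intercept) in x = m y + c form."""
    ys = np.asarray(y_samples, dtype=float)
    if ys.size == 0:
        raise ValueError("y_samples must be nonempty")
    x1 = gt[0] * ys + gt[1]
    x2 = fit[0] * ys + fit[1]
    return float(np.mean(np.abs(x1 - x2)))


def evaluate_image(
    gt_rows: Sequence[tuple[float, float]],
    fitted_rows: Sequence[tuple[float, float]],
    cfg: EvalConfig | None = None,
) -> list[RowMatch]:
    """Match fitted rows to ground truth and score each ground-truth row.

    Matching is greedy one-to-one by smallest center deviation.  Unmatched
    ground-truth rows (fewer fitted than true rows) count as invalid with
    theta = delta = infinity.  Validity: theta < validity_threshold.
    """
    if len(gt_rows) == 0:
        raise ValueError("gt_rows must be nonempty")
    cfg = cfg or EvalConfig()
    pairs = sorted(
        (
            (center_deviation(gt, fit, cfg.y_samples), gi, fi)
            for gi, gt in enumerate(gt_rows)
            for fi, fit in enumerate(fitted_rows)
        ),
    )
    gt_used: dict[int, int] = {}
    fit_used: set[int] = set()
    for _, gi, fi in pairs:
        if gi in gt_used or fi in fit_used:
            continue
        gt_used[gi] = fi
        fit_used.add(fi)
    matches = []
    for gi, gt in enumerate(gt_rows):
        if gi in gt_used:
            fit = fitted_rows[gt_used[gi]]
            theta = angular_error(gt[0], fit[0])
            delta = center_deviation(gt, fit, cfg.y_samples)
            matches.append(
                RowMatch(
                    gt_slope=gt[0],
                    gt_intercept=gt[1],
                    fitted_slope=fit[0],
                    fitted_intercept=fit[1],
                    theta=theta,
                    delta=delta,
                    valid=theta < cfg.validity_threshold,
                )
            )
        else:
            matches.append(
                RowMatch(
                    gt_slope=gt[0],
                    gt_intercept=gt[1],
                    fitted_slope=None,
                    fitted_intercept=None,
                    theta=math.inf,
                    delta=math.inf,
                    valid=False,
                )
            )
    return matches


def aggregate(
    per_image: Sequence[Sequence[RowMatch]],
    times_ms: Sequence[float] | None = None,
) -> EvalAggregates:
    """Dataset-level aggregates: theta and delta are averaged per image
    first, then across images (images with no matched rows contribute to
    the validity rate but not to the theta/delta means); the validity rate
    pools valid rows over all ground-truth rows; FPS = 1000 / mean time."""
    if len(per_image) == 0:
        raise ValueError("need at least one image")
    theta_means, delta_means = [], []
    n_valid = n_rows = 0
    for matches in per_image:
        matched = [m for m in matches if m.matched]
        n_rows += len(matches)
        n_valid += sum(m.valid for m in matches)
        if matched:
            theta_means.append(float(np.mean([m.theta for m in matched])))
            delta_means.append(float(np.mean([m.delta for m in matched])))
    mean_theta = float(np.mean(theta_means)) if theta_means else math.nan
    sd_theta = float(np.std(theta_means)) if theta_means else math.nan
    mean_delta = float(np.mean(delta_means)) if delta_means else math.nan
    sd_delta = float(np.std(delta_means)) if delta_means else math.nan
    if times_ms is not None and len(times_ms) > 0:
        mean_time = float(np.mean(times_ms))
        fps = 1000.0 / mean_time if mean_time > 0 else math.inf
    else:
        mean_time = math.nan
        fps = math.nan
    return EvalAggregates(
        mean_theta=mean_theta,
        sd_theta=sd_theta,
        mean_delta=mean_delta,
        sd_delta=sd_delta,
        validity_rate=n_valid / n_rows if n_rows else math.nan,
        mean_time_ms=mean_time,
        fps=fps,
        n_images=len(per_image),
        n_rows=n_rows,
    )


# ---------------------------------------------------------------------------
# detection metrics


@dataclass(frozen=True)
class PRResult:
    precision: float
    recall: float
    ap: float
    map50: float
    curve: tuple[tuple[float, float], ...]  # (recall, precision) points


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two (cx, cy, w, h) boxes."""
    ax0, ay0 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax1, ay1 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx1, by1 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def detection_pr(
    pred_boxes: np.ndarray,
    confidences: Sequence[float],
    gt_boxes: np.ndarray,
    iou_threshold: float = 0.5,
) -> PRResult:
    """Single-class precision / recall / average precision at an IoU cut.

    Predictions are processed in confidence-descending order; each is a true
    positive if it overlaps an unmatched ground-truth box with IoU >= the
    threshold.  AP is the area under the monotone (all-point) precision
    envelope of the resulting PR curve; with one class mAP@0.5 equals AP.
    """
    pred = np.asarray(pred_boxes, dtype=float).reshape(-1, 4)
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    conf = np.asarray(confidences, dtype=float)
    if len(gt) == 0:
        raise ValueError("recall undefined with zero ground-truth boxes")
    if len(conf) != len(pred):
        raise ValueError("one confidence per prediction required")
    order = np.argsort(-conf, kind="stable")
    matched: set[int] = set()
    tp_flags = []
    for pi in order:
        best_iou, best_gi = 0.0, None
        for gi in range(len(gt)):
            if gi in matched:
                continue
            v = _iou(pred[pi], gt[gi])
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None and best_iou >= iou_threshold:
            matched.add(best_gi)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum([not f for f in tp_flags])
    recalls = tp_cum / len(gt)
    precisions = tp_cum / (tp_cum + fp_cum)
    # monotone envelope from the right, integrated over recall
    if len(pred) == 0:
        return PRResult(0.0, 0.0, 0.0, 0.0, ())
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recalls, env):
        ap += (r - r_prev) * p
        r_prev = r
    precision = float(precisions[-1])
    recall = float(recalls[-1])
    curve = tuple((float(r), float(p)) for r, p in zip(recalls, precisions))
    return PRResult(precision, recall, float(ap), float(ap), curve)
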