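"""Row extraction: 1-D density clustering, centerline fitting, row selection.

After inverse perspective mapping, plant centers of one crop row share
nearly the same transverse coordinate x', so clustering uses x' alone.
Each cluster is a candidate row; clusters with too few plants (typically
half-visible border rows) are discarded; a centerline x' = m y' + c is
fitted per row with one of three interchangeable fitters (least squares,
PCA, RANSAC); finally the two rows nearest the image midpoint are selected
as the navigation reference.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import (
    Homography,
    PointAtInfinityError,
    backproject_line,
    line_to_image_space,
    transform_points,
)

__all__ = [
    "NOISE",
    "Fitter",
    "ClusterParams",
    "RowLine",
    "RowExtractionResult",
    "DegenerateFitError",
    "dbscan_1d",
    "remove_small_clusters",
    "fit_lsm",
    "fit_pca",
    "fit_ransac",
    "fit_points",
    "select_center_rows",
    "extract_rows",
]

NOISE = -1


class Fitter(str, Enum):
    LSM = "lsm"
    PCA = "pca"
    RANSAC = "ransac"


class DegenerateFitError(ValueError):
    """Raised when a cluster admits no line of the form x' = m y' + c."""


@dataclass(frozen=True)
class ClusterParams:
    """Density-clustering parameters.

    eps
        Neighborhood radius in IPM x' units.  A practical heuristic is
        ~0.25 x the expected row spacing in destination-plane units.
    min_samples
        Minimum neighborhood size (the point itself counts) for a core point.
    min_row_size
        Clusters with fewer members are relabeled noise afterwards; plants
        at the image border rarely form a complete row, so plant count per
        cluster serves as a completeness indicator.
    """

    eps: float
    min_samples: int = 3
    min_row_size: int = 4

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_row_size < 1:
            raise ValueError("min_row_size must be >= 1")


@dataclass(frozen=True)
class RowLine:
    """Fitted crop-row centerline x' = m y' + c in IPM space."""

    m: float
    c: float
    n_points: int
    fitter: Fitter

    def x_at(self, y: float) -> float:
        return self.m * y + self.c


@dataclass
class RowExtractionResult:
    all_rows: list[RowLine]
    selected: list[int]
    image_segments: list[np.ndarray]
    noise_count: int
    timing_ms: dict[str, float] = field(default_factory=dict)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def dbscan_1d(xs: Sequence[float], params: ClusterParams) -> np.ndarray:
    """Density-based clustering of transverse coordinates.

    Standard DBSCAN on the metric |xj' - xi'|: a point whose eps-neighborhood
    (itself included) holds at least ``min_samples`` points is a core point;
    clusters are maximal density-connected sets of core points plus the
    border points in reach.  A border point reachable from several clusters
    is assigned to its nearest core point (ties to the smaller x'), which
    makes the labeling independent of input order.  Cluster ids are
    contiguous from 0 and ordered by increasing cluster mean x'.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.ndim != 1:
        raise ValueError("xs must be one-dimensional")
    n = len(xs)
    if n == 0:
        return np.empty(0, dtype=int)
    if not np.all(np.isfinite(xs)):
        raise ValueError("xs contains non-finite values")

    order = np.argsort(xs, kind="stable")
    sx = xs[order]
    # neighbor ranges in the sorted array: [lo[i], hi[i])
    lo = np.searchsorted(sx, sx - params.eps, side="left")
    hi = np.searchsorted(sx, sx + params.eps, side="right")
    core = (hi - lo) >= params.min_samples

    labels_sorted = np.full(n, NOISE, dtype=int)
    # connected components of core points: consecutive cores within eps chain
    cid = -1
    core_idx = np.flatnonzero(core)
    prev = None
    for i in core_idx:
        if prev is None or sx[i] - sx[prev] > params.eps:
            cid += 1
        labels_sorted[i] = cid
        prev = i
    # border points: non-core within eps of a core; nearest core wins,
    # ties to the smaller x' (the left core)
    if core_idx.size:
        core_x = sx[core_idx]
        for i in np.flatnonzero(~core):
            j = np.searchsorted(core_x, sx[i])
            best = None
            if j > 0:
                best = (sx[i] - core_x[j - 1], core_idx[j - 1])
            if j < len(core_x):
                d = core_x[j] - sx[i]
                if best is None or d < best[0]:
                    best = (d, core_idx[j])
            if best is not None and best[0] <= params.eps:
                labels_sorted[i] = labels_sorted[best[1]]

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return _canonicalize_labels(xs, labels)


def _canonicalize_labels(xs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of increasing cluster mean x'."""
    ids = [int(c) for c in np.unique(labels) if c != NOISE]
    if not ids:
        return labels
    means = {c: float(xs[labels == c].mean()) for c in ids}
    ranked = sorted(ids, key=lambda c: means[c])
    remap = {c: r for r, c in enumerate(ranked)}
    out = labels.copy()
    for c, r in remap.items():
        out[labels == c] = r
    return out


def remove_small_clusters(
    xs: Sequence[float], labels: np.ndarray, min_row_size: int
) -> np.ndarray:
    """Relabel clusters with fewer than ``min_row_size`` members as noise.

    Remaining ids are recompacted, preserving the mean-x' ordering.
    """
    xs = np.asarray(xs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    for c in np.unique(labels):
        if c == NOISE:
            continue
        if np.count_nonzero(labels == c) < min_row_size:
            out[labels == c] = NOISE
    return _canonicalize_labels(xs, out)


def fit_lsm(points: np.ndarray) -> RowLine:
    """Closed-form least-squares centerline with y' as independent variable.

    m = sum((y'-ybar)(x'-xbar)) / sum((y'-ybar)^2),  c = xbar - m ybar.
    Rows extend along y' (the travel direction), so residuals are measured
    transversely in x'.
    """
    pts = _as_points(points, min_n=2)
    x, y = pts[:, 0], pts[:, 1]
    ybar, xbar = y.mean(), x.mean()
    syy = float(((y - ybar) ** 2).sum())
    if syy <= 1e-300:
        raise DegenerateFitError(
            "all y' identical: row perpendicular to travel direction"
        )
    m = float(((y - ybar) * (x - xbar)).sum()) / syy
    c = xbar - m * ybar
    return RowLine(m=m, c=float(c), n_points=len(pts), fitter=Fitter.LSM)


def fit_pca(points: np.ndarray) -> RowLine:
    """Principal-axis centerline: the line through the centroid along the
    dominant eigenvector of the 2x2 covariance of (y', x')."""
    pts = _as_points(points, min_n=2)
    x, y = pts[:, 0], pts[:, 1]
    centered = np.column_stack([y - y.mean(), x - x.mean()])
    if np.allclose(centered, 0):
        raise DegenerateFitError("all points coincide")
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]  # (dy', dx')
    if abs(direction[0]) < 1e-12:
        raise DegenerateFitError(
            "principal direction has zero y' component (horizontal row)"
        )
    m = float(direction[1] / direction[0])
    c = float(x.mean() - m * y.mean())
    return RowLine(m=m, c=c, n_points=len(pts), fitter=Fitter.PCA)


def fit_ransac(
    points: np.ndarray,
    inlier_tol: float = 2.0,
    n_iter: int = 100,
    seed: int = 0,
) -> RowLine:
    """Random-sample-consensus centerline fit.

    Repeatedly draws 2-point hypotheses, scores them by inlier count under
    the transverse residual |x' - (m y' + c)| <= inlier_tol (ties broken by
    lower total inlier residual), then refits the best inlier set with
    :func:`fit_lsm`.  Deterministic for a given seed.
    """
    pts = _as_points(points, min_n=2)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = len(pts)
    if n == 2:
        return _refit(pts, np.ones(n, dtype=bool))
    rng = np.random.default_rng(seed)
    x, y = pts[:, 0], pts[:, 1]
    best: tuple[int, float, np.ndarray] | None = None
    for _ in range(n_iter):
        i, j = rng.choice(n, size=2, replace=False)
        dy = y[j] - y[i]
        if abs(dy) < 1e-12:
            continue
        m = (x[j] - x[i]) / dy
        c = x[i] - m * y[i]
        resid = np.abs(x - (m * y + c))
        inliers = resid <= inlier_tol
        count = int(inliers.sum())
        total = float(resid[inliers].sum())
        if best is None or count > best[0] or (count == best[0] and total < best[1]):
            best = (count, total, inliers)
    if best is None or best[0] < 2:
        raise DegenerateFitError("no non-degenerate 2-point hypothesis found")
    return _refit(pts, best[2])


def _refit(pts: np.ndarray, inliers: np.ndarray) -> RowLine:
    line = fit_lsm(pts[inliers])
    return RowLine(m=line.m, c=line.c, n_points=int(inliers.sum()), fitter=Fitter.RANSAC)


def fit_points(points: np.ndarray, fitter: Fitter | str, **kwargs) -> RowLine:
    """Dispatch to the named fitter (RANSAC kwargs: inlier_tol, n_iter, seed)."""
    fitter = Fitter(fitter)
    if fitter is Fitter.LSM:
        return fit_lsm(points)
    if fitter is Fitter.PCA:
        return fit_pca(points)
    return fit_ransac(points, **kwargs)


def _as_points(points: np.ndarray, min_n: int) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < min_n or pts.shape[1] != 2:
        raise ValueError(f"need at least {min_n} (x', y') points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    return pts


def select_center_rows(
    rows: Sequence[RowLine],
    h: Homography,
    image_width: float,
    image_height: float,
    y_ref: float | None = None,
) -> list[int]:
    """Pick the (up to) two rows nearest the image midpoint.

    Each row's centerline is back-projected to image space and evaluated at
    the reference height (default: half the image height); the two rows with
    the smallest |x - width/2| are selected, ties going to the smaller x.
    Rows that are horizontal in image space are ranked last.
    """
    if y_ref is None:
        y_ref = image_height / 2.0
    mid_x = image_width / 2.0
    keyed = []
    for idx, row in enumerate(rows):
        try:
            m_img, c_img = line_to_image_space(h, row.m, row.c)
            x = m_img * y_ref + c_img
            keyed.append((abs(x - mid_x), x, idx))
        except PointAtInfinityError:
            keyed.append((math.inf, math.inf, idx))
    keyed.sort()
    return [idx for _, _, idx in keyed[:2]]


def extract_rows(
    detections: np.ndarray,
    h: Homography,
    cparams: ClusterParams,
    fitter: Fitter | str = Fitter.LSM,
    image_size: tuple[float, float] = (640, 480),
    y_ref: float | None = None,
    ransac_tol: float = 2.0,
    ransac_iter: int = 100,
    seed: int = 0,
) -> RowExtractionResult:
    """Full pipeline: IPM -> 1-D clustering -> small-cluster removal ->
    per-row centerline fit -> back-projection -> navigation-row selection.

    ``detections`` are pixel centers (N, 2); ``h`` maps image -> IPM plane.
    Deterministic for LSM/PCA, seed-deterministic for RANSAC.  Per-stage
    wall-clock milliseconds are recorded in ``timing_ms``.
    """
    fitter = Fitter(fitter)
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    timing: dict[str, float] = {}
    width, height = image_size

    t0 = time.perf_counter()
    ipm = transform_points(h, det) if len(det) else np.empty((0, 2))
    timing["ipm"] = (time.perf_counter() - t0) * 1000

    t0 = time.perf_counter()
    labels = dbscan_1d(ipm[:, 0], cparams)
    labels = remove_small_clusters(ipm[:, 0], labels, cparams.min_row_size)
    timing["cluster"] = (time.perf_counter() - t0) * 1000

    t0 = time.perf_counter()
    rows: list[RowLine] = []
    segments: list[np.ndarray] = []
    n_clusters = int(labels.max()) + 1 if labels.size else 0
    for cid in range(n_clusters):
        pts = ipm[labels == cid]
        try:
            if fitter is Fitter.RANSAC:
                row_seed = (seed + cid) % (2**31)
                line = fit_ransac(pts, inlier_tol=ransac_tol, n_iter=ransac_iter, seed=row_seed)
            else:
                line = fit_points(pts, fitter)
        except DegenerateFitError as exc:
            raise DegenerateFitError(f"fit stage, cluster {cid}: {exc}") from exc
        rows.append(line)
        y_lo, y_hi = float(pts[:, 1].min()), float(pts[:, 1].max())
        if y_lo == y_hi:
            y_lo, y_hi = y_lo - 0.5, y_hi + 0.5
        segments.append(backproject_line(h, line.m, line.c, (y_lo, y_hi)))
    timing["fit"] = (time.perf_counter() - t0) * 1000

    t0 = time.perf_counter()
    selected = select_center_rows(rows, h, width, height, y_ref=y_ref)
    timing["select"] = (time.perf_counter() - t0) * 1000

    return RowExtractionResult(
        all_rows=rows,
        selected=selected,
        image_segments=segments,
        noise_count=int(np.count_nonzero(labels == NOISE)),
        timing_ms=timing,
        labels=labels,
    )
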