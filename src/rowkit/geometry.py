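"""Planar homographies for inverse perspective mapping (IPM).

Field images of row crops show parallel rows converging toward the top of
the frame.  A single projective transform (the IPM matrix ``M``) estimated
from four manually chosen point correspondences maps the image onto a
quasi-top-view ground plane where rows are parallel again, which makes
one-dimensional clustering of plant centers possible.  The inverse matrix
``M^-1`` projects fitted row centerlines back into image space for display
and navigation.

Coordinate convention: image origin top-left, x rightward, y downward,
units pixels.  The IPM plane inherits the units of the destination points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Homography",
    "CorrespondenceSet",
    "DegenerateCorrespondenceError",
    "PointAtInfinityError",
    "estimate_homography",
    "transform_point",
    "transform_points",
    "invert_homography",
    "backproject_line",
    "line_to_image_space",
]

#: singularity guard for homogeneous normalization and matrix inversion
_SINGULAR_TOL = 1e-12


class DegenerateCorrespondenceError(ValueError):
    """Raised when the four-point correspondence cannot define a homography."""


class PointAtInfinityError(ValueError):
    """Raised when a transformed point has a vanishing homogeneous component."""


@dataclass(frozen=True)
class Homography:
    """A 3x3 invertible matrix acting on homogeneous 2-D coordinates.

    Normalized so that ``m[2, 2] == 1`` whenever that entry is nonzero.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography contains non-finite entries")
        if abs(m[2, 2]) > _SINGULAR_TOL:
            m = m / m[2, 2]
        if abs(np.linalg.det(m)) <= _SINGULAR_TOL:
            raise ValueError("homography is singular (|det| <= 1e-12)")
        object.__setattr__(self, "m", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def as_flat_list(self) -> list[float]:
        """Row-major 9-number representation for result JSON."""
        return [float(v) for v in self.m.ravel()]

    @classmethod
    def from_flat_list(cls, values: Sequence[float]) -> "Homography":
        arr = np.asarray(values, dtype=float)
        if arr.size != 9:
            raise ValueError("expected 9 numbers (row-major 3x3)")
        return cls(arr.reshape(3, 3))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Four source/destination point pairs defining the IPM.

    No three points in either set may be collinear, and points must be
    pairwise distinct; otherwise the direct linear solve is degenerate.
    """

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        for name, pts in (("src", src), ("dst", dst)):
            if pts.shape != (4, 2):
                raise ValueError(f"{name} must be 4 (x, y) points, got {pts.shape}")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"{name} contains non-finite coordinates")
            _check_nondegenerate(pts, name)
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)


def _check_nondegenerate(pts: np.ndarray, name: str) -> None:
    scale = max(1.0, float(np.abs(pts).max()))
    for i in range(4):
        for j in range(i + 1, 4):
            if np.allclose(pts[i], pts[j], atol=1e-9 * scale):
                raise DegenerateCorrespondenceError(
                    f"{name} points {i} and {j} coincide"
                )
            for k in range(j + 1, 4):
                a, b, c = pts[i], pts[j], pts[k]
                cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                if abs(cross) <= 1e-9 * scale * scale:
                    raise DegenerateCorrespondenceError(
                        f"{name} points {i}, {j}, {k} are collinear"
                    )


def estimate_homography(corr: CorrespondenceSet) -> Homography:
    """Estimate the IPM matrix from four exact point correspondences.

    Solves the standard 8-unknown direct linear system with ``h33`` fixed
    to 1.  Each pair contributes two equations::

        x' = (h11 x + h12 y + h13) / (h31 x + h32 y + 1)
        y' = (h21 x + h22 y + h23) / (h31 x + h32 y + 1)

    Raises
    ------
    DegenerateCorrespondenceError
        If the configuration is degenerate (checked up front) or the
        linear system is singular despite passing the geometric check.
    """
    src, dst = corr.src, corr.dst
    a = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        b[2 * i] = u
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCorrespondenceError(
            f"correspondence system is singular: {exc}"
        ) from exc
    m = np.append(h, 1.0).reshape(3, 3)
    return Homography(m)


def transform_point(h: Homography, p: Sequence[float]) -> tuple[float, float]:
    """Map one point through the homography with homogeneous normalization.

    Returns ``(u/w, v/w)`` where ``(u, v, w) = M [x, y, 1]^T``.
    """
    x, y = float(p[0]), float(p[1])
    u, v, w = h.m @ (x, y, 1.0)
    if abs(w) < _SINGULAR_TOL:
        raise PointAtInfinityError(
            f"point ({x}, {y}) maps to infinity (|w| = {abs(w):.3e})"
        )
    return (u / w, v / w)


def transform_points(h: Homography, pts: Iterable[Sequence[float]]) -> np.ndarray:
    """Vectorized :func:`transform_point` for an (N, 2) array of points."""
    arr = np.atleast_2d(np.asarray(list(pts) if not isinstance(pts, np.ndarray) else pts, dtype=float))
    if arr.size == 0:
        return np.empty((0, 2))
    homog = np.column_stack([arr, np.ones(len(arr))])
    out = homog @ h.m.T
    w = out[:, 2]
    if np.any(np.abs(w) < _SINGULAR_TOL):
        bad = int(np.argmin(np.abs(w)))
        raise PointAtInfinityError(f"point index {bad} maps to infinity")
    return out[:, :2] / w[:, None]


def invert_homography(h: Homography) -> Homography:
    """Return ``M^-1``, renormalized so the bottom-right entry is 1."""
    try:
        inv = np.linalg.inv(h.m)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by invariant
        raise ValueError(f"homography is not invertible: {exc}") from exc
    return Homography(inv)


def backproject_line(
    h: Homography,
    slope: float,
    intercept: float,
    y_prime_range: tuple[float, float],
) -> np.ndarray:
    """Project an IPM-space centerline ``x' = m y' + c`` back to image space.

    Evaluates the line at the two bounds of ``y_prime_range`` and maps both
    endpoints through ``M^-1``.  Returns a (2, 2) array of pixel endpoints.
    """
    y0, y1 = float(y_prime_range[0]), float(y_prime_range[1])
    if not np.isfinite([y0, y1]).all() or y0 == y1:
        raise ValueError("y_prime_range must be a nonempty finite interval")
    inv = invert_homography(h)
    endpoints = [(slope * y + intercept, y) for y in (y0, y1)]
    return np.array([transform_point(inv, p) for p in endpoints])


def line_to_image_space(h: Homography, slope: float, intercept: float) -> tuple[float, float]:
    """Convert an IPM-space line ``x' = m y' + c`` to image-space ``x = m y + c``.

    The IPM line in homogeneous line coordinates is ``l' = (1, -m, -c)``;
    a point ``p`` lies on the image of the line iff ``(M^T l') . p = 0``,
    so the image line is ``M^T l'``.  Raises :class:`PointAtInfinityError`
    if the image line is horizontal (no x-as-function-of-y form).
    """
    a, b, c0 = h.m.T @ (1.0, -slope, -intercept)
    scale = max(abs(a), abs(b), abs(c0), 1.0)
    if abs(a) < _SINGULAR_TOL * scale:
        raise PointAtInfinityError("line is horizontal in image space")
    # a x + b y + c0 = 0  ->  x = (-b/a) y + (-c0/a)
    return (-b / a, -c0 / a)
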