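"""Synthetic maize field scenes with known row geometry.

The generator stands in for field imagery that is not publicly available.
It models exactly the structure the row-extraction pipeline consumes:
parallel crop rows on a flat ground plane at fixed spacing, plants at
regular intervals along each row with lateral Gaussian jitter, random
plant dropout (missed detections / missing emergence), and uniform
off-row outlier points (weeds, false detections).  The ground plane is
projected into the camera image by a single ground-to-image homography —
the calibration-free counterpart of the perspective that makes real rows
converge toward the top of the frame.

What it does not model: plant appearance, illumination, occlusion-driven
correlated detection errors, or curved rows.  Passing tests on these
scenes therefore validates the geometry/clustering/fitting chain, not the
upstream detector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import (
    CorrespondenceSet,
    Homography,
    estimate_homography,
    invert_homography,
    transform_points,
)

__all__ = ["SceneConfig", "SceneTruth", "generate_scene", "write_scene", "DEFAULT_CORRESPONDENCE"]

# Documented default camera pose: a bottom-wide trapezoid in the 640x480
# image maps to an axis-aligned rectangle on the ground plane, reproducing
# the convergence of rows toward the image top.
DEFAULT_SRC = ((100.0, 440.0), (540.0, 440.0), (250.0, 120.0), (390.0, 120.0))
DEFAULT_DST = ((100.0, 440.0), (540.0, 440.0), (100.0, 120.0), (540.0, 120.0))
DEFAULT_CORRESPONDENCE = CorrespondenceSet(src=np.array(DEFAULT_SRC), dst=np.array(DEFAULT_DST))


@dataclass(frozen=True)
class SceneConfig:
    """Scene parameters.

    Ground units equal destination-plane pixels of the default rectified
    view.  ``row_spacing`` (default 80) and ``plant_spacing`` (default 28)
    give 5 rows x 12 plants filling the rectified region.  ``row_heading``
    is degrees from vertical (0 = rows parallel to the travel direction).
    """

    image_width: int = 640
    image_height: int = 480
    n_rows: int = 5
    n_plants_per_row: int = 12
    row_spacing: float = 80.0
    plant_spacing: float = 28.0
    lateral_jitter_sd: float = 0.0
    dropout_p: float = 0.0
    n_outliers: int = 0
    row_heading: float = 0.0
    box_size: float = 24.0
    confidence_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be positive")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.lateral_jitter_sd < 0:
            raise ValueError("lateral_jitter_sd must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    Row lines are (slope, intercept) pairs in x = m y + c form, reported in
    both ground and image coordinates; plant and outlier points are image
    pixels; ``correspondence`` estimates the true image->ground IPM.
    """

    config: SceneConfig
    gt_rows_ground: list[tuple[float, float]]
    gt_rows_image: list[tuple[float, float]]
    plant_points: np.ndarray  # (N, 2) image pixels
    plant_row_labels: np.ndarray  # (N,) row index
    plant_points_ground: np.ndarray
    outlier_points: np.ndarray  # (K, 2) image pixels
    correspondence: CorrespondenceSet
    homography_ground_to_image: Homography

    @property
    def ipm(self) -> Homography:
        """The true image -> ground (IPM) homography."""
        return invert_homography(self.homography_ground_to_image)

    @property
    def all_detection_points(self) -> np.ndarray:
        """Plant centers followed by outliers, as the detector would emit."""
        if len(self.outlier_points) == 0:
            return self.plant_points
        if len(self.plant_points) == 0:
            return self.outlier_points
        return np.vstack([self.plant_points, self.outlier_points])


def _ground_region(corr: CorrespondenceSet) -> tuple[float, float, float, float]:
    dst = corr.dst
    return (
        float(dst[:, 0].min()),
        float(dst[:, 0].max()),
        float(dst[:, 1].min()),
        float(dst[:, 1].max()),
    )


def generate_scene(
    cfg: SceneConfig,
    correspondence: CorrespondenceSet = DEFAULT_CORRESPONDENCE,
) -> SceneTruth:
    """Generate one scene, deterministic for a given ``cfg.seed``.

    Rows are laid out on the ground plane centered in the rectified region,
    plants dropped independently with probability ``dropout_p``, lateral
    jitter drawn N(0, sigma) perpendicular to the row direction, outliers
    uniform over the ground region; everything is projected to image pixels
    through the ground-to-image homography implied by ``correspondence``.
    """
    rng = np.random.default_rng(cfg.seed)
    ipm = estimate_homography(correspondence)  # image -> ground
    g2i = invert_homography(ipm)

    x_min, x_max, y_min, y_max = _ground_region(correspondence)
    cx = (x_min + x_max) / 2.0
    heading = math.radians(cfg.row_heading)
    m_ground = math.tan(heading)  # dx/dy, 0 for vertical rows
    direction = np.array([math.sin(heading), math.cos(heading)])
    normal = np.array([math.cos(heading), -math.sin(heading)])

    span = (cfg.n_plants_per_row - 1) * cfg.plant_spacing
    y_start = (y_min + y_max - span) / 2.0
    y_anchor = (y_min + y_max) / 2.0

    gt_ground: list[tuple[float, float]] = []
    gt_image: list[tuple[float, float]] = []
    pts_ground: list[np.ndarray] = []
    labels: list[int] = []
    for r in range(cfg.n_rows):
        x_r = cx + (r - (cfg.n_rows - 1) / 2.0) * cfg.row_spacing
        # row line through (x_r, y_anchor) with slope m_ground
        c_ground = x_r - m_ground * y_anchor
        gt_ground.append((m_ground, c_ground))
        gt_image.append(_line_ground_to_image(g2i, m_ground, c_ground))
        base = np.array([x_r + m_ground * (y_start - y_anchor), y_start])
        for j in range(cfg.n_plants_per_row):
            if cfg.dropout_p > 0 and rng.random() < cfg.dropout_p:
                continue
            p = base + direction * (j * cfg.plant_spacing)
            if cfg.lateral_jitter_sd > 0:
                p = p + normal * rng.normal(0.0, cfg.lateral_jitter_sd)
            pts_ground.append(p)
            labels.append(r)

    outliers_ground = np.column_stack(
        [
            rng.uniform(x_min, x_max, cfg.n_outliers),
            rng.uniform(y_min, y_max, cfg.n_outliers),
        ]
    ) if cfg.n_outliers else np.empty((0, 2))

    pts_ground_arr = np.array(pts_ground) if pts_ground else np.empty((0, 2))
    plant_img = transform_points(g2i, pts_ground_arr) if len(pts_ground_arr) else np.empty((0, 2))
    outlier_img = transform_points(g2i, outliers_ground) if len(outliers_ground) else np.empty((0, 2))

    return SceneTruth(
        config=cfg,
        gt_rows_ground=gt_ground,
        gt_rows_image=gt_image,
        plant_points=plant_img,
        plant_row_labels=np.array(labels, dtype=int),
        plant_points_ground=pts_ground_arr,
        outlier_points=outlier_img,
        correspondence=correspondence,
        homography_ground_to_image=g2i,
    )


def _line_ground_to_image(g2i: Homography, m: float, c: float) -> tuple[float, float]:
    """Map a ground line x = m y + c to image space x = m' y + c'.

    Line coords: ground line l_g = (1, -m, -c); image points p satisfy
    l_g . (G^-1 p) = 0, i.e. the image line is (G^-1)^T l_g = (G^T)^-1 l_g.
    """
    ipm = invert_homography(g2i)
    a, b, c0 = ipm.m.T @ (1.0, -m, -c)
    if abs(a) < 1e-12:
        raise ValueError("row is horizontal in image space")
    return (-b / a, -c0 / a)


def write_scene(
    truth: SceneTruth,
    out_dir: str | Path,
    stem: str = "scene",
    render: bool = False,
) -> dict[str, Path]:
    """Write a scene as YOLO label text plus a JSON ground-truth file.

    Labels: one line per detection, ``class cx cy w h [conf]`` with
    normalized coordinates; plants and outliers all carry class 0 (the
    detector sees a single maize class).  A confidence column is emitted
    when ``confidence_noise > 0``.  With ``render=True`` a PNG overlay is
    drawn via matplotlib (optional dependency).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1)

    label_path = out_dir / f"{stem}.txt"
    lines = []
    for p in truth.all_detection_points:
        cx = p[0] / cfg.image_width
        cy = p[1] / cfg.image_height
        bw = cfg.box_size / cfg.image_width
        bh = cfg.box_size / cfg.image_height
        fields = [0, cx, cy, bw, bh]
        if cfg.confidence_noise > 0:
            conf = float(np.clip(rng.normal(0.9, cfg.confidence_noise), 0.05, 1.0))
            fields.append(conf)
        lines.append(
            " ".join("0" if i == 0 else f"{v:.6f}" for i, v in enumerate(fields))
        )
    label_path.write_text("\n".join(lines) + ("\n" if lines else ""))

    truth_path = out_dir / f"{stem}_truth.json"
    payload = {
        "schema_version": 1,
        "config": asdict(cfg),
        "gt_rows_ground": [list(r) for r in truth.gt_rows_ground],
        "gt_rows_image": [list(r) for r in truth.gt_rows_image],
        "plant_points": truth.plant_points.round(6).tolist(),
        "plant_row_labels": truth.plant_row_labels.tolist(),
        "outlier_points": truth.outlier_points.round(6).tolist(),
        "correspondence": {
            "src": truth.correspondence.src.tolist(),
            "dst": truth.correspondence.dst.tolist(),
        },
    }
    truth_path.write_text(json.dumps(payload, indent=2) + "\n")

    paths = {"labels": label_path, "truth": truth_path}
    if render:
        paths["png"] = _render_scene(truth, out_dir / f"{stem}.png")
    return paths


def read_truth(path: str | Path) -> dict:
    """Load a ``*_truth.json`` file written by :func:`write_scene`."""
    with open(path) as fh:
        data = json.load(fh)
    if "gt_rows_image" not in data:
        raise ValueError(f"{path} is not a scene truth file")
    return data


def _render_scene(truth: SceneTruth, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = truth.config
    fig, ax = plt.subplots(figsize=(6.4, 4.8))
    if len(truth.plant_points):
        ax.scatter(truth.plant_points[:, 0], truth.plant_points[:, 1], c=truth.plant_row_labels, s=18)
    if len(truth.outlier_points):
        ax.scatter(truth.outlier_points[:, 0], truth.outlier_points[:, 1], marker="x", c="red", s=24)
    ys = np.array([0.0, cfg.image_height])
    for m, c in truth.gt_rows_image:
        ax.plot(m * ys + c, ys, "g--", lw=1)
    ax.set_xlim(0, cfg.image_width)
    ax.set_ylim(cfg.image_height, 0)
    ax.set_title("synthetic scene (image space)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
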