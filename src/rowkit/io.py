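"""Readers and writers: YOLO label text, point CSV, IPM config, result JSON.

All readers validate rather than coerce: malformed lines raise with the
offending line or row number.  Result JSON files are schema-versioned and
store floats at six decimals, enough to round-trip slopes and pixel
coordinates at the tolerances the pipeline works to.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .evaluation import EvalAggregates
from .geometry import CorrespondenceSet, Homography
from .rows import RowExtractionResult

__all__ = [
    "DetectionRecord",
    "LabelFormatError",
    "read_yolo_labels",
    "read_points_csv",
    "read_correspondence",
    "write_result_json",
    "read_result_json",
]

SCHEMA_VERSION = 1


class LabelFormatError(ValueError):
    """Malformed detection or point file; message names the line/row."""


@dataclass(frozen=True)
class DetectionRecord:
    class_id: int
    cx: float
    cy: float
    bw: float
    bh: float
    confidence: float | None = None


def read_yolo_labels(
    path: str | Path,
    image_width: float,
    image_height: float,
    classes: set[int] | None = None,
) -> tuple[list[DetectionRecord], np.ndarray]:
    """Parse a YOLO label file into records plus pixel centers.

    Dialect: whitespace-separated ``class cx cy w h [conf]`` per nonempty
    line, coordinates normalized to [0, 1].  ``classes=None`` accepts every
    class (a single maize class is the common case).  Returns the records
    and an (N, 2) array of pixel centers (cx * W, cy * H).
    """
    records: list[DetectionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise LabelFormatError(
                    f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
                )
            try:
                class_id = int(fields[0])
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise LabelFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if class_id < 0:
                raise LabelFormatError(f"{path}:{lineno}: negative class id")
            cx, cy, bw, bh = values[:4]
            for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, bw, bh)):
                if not (0.0 <= v <= 1.0):
                    raise LabelFormatError(
                        f"{path}:{lineno}: {name}={v} outside normalized range [0, 1]"
                    )
            conf = values[4] if len(values) == 5 else None
            if conf is not None and not (0.0 <= conf <= 1.0):
                raise LabelFormatError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
            if classes is not None and class_id not in classes:
                continue
            records.append(DetectionRecord(class_id, cx, cy, bw, bh, conf))
    centers = np.array(
        [[r.cx * image_width, r.cy * image_height] for r in records]
    ).reshape(-1, 2)
    return records, centers


def read_points_csv(path: str | Path) -> np.ndarray:
    """Read an (N, 2) pixel point list from a CSV with header ``x,y``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
            raise LabelFormatError(f"{path}: missing required columns x,y")
        points = []
        for idx, row in enumerate(reader, start=1):
            if row["x"] is None or (row["x"] == "" and row["y"] in ("", None)):
                continue  # blank line
            try:
                points.append((float(row["x"]), float(row["y"])))
            except (TypeError, ValueError) as exc:
                raise LabelFormatError(f"{path}: row {idx}: non-numeric cell") from exc
    return np.array(points).reshape(-1, 2)


def read_correspondence(path: str | Path) -> CorrespondenceSet:
    """Load a four-point IPM correspondence from YAML or JSON.

    Expected structure: ``{src: [[x, y] x4], dst: [[x, y] x4]}``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "src" not in data or "dst" not in data:
        raise LabelFormatError(f"{path}: expected mapping with 'src' and 'dst' keys")
    return CorrespondenceSet(src=np.asarray(data["src"], float), dst=np.asarray(data["dst"], float))


def _round6(value):
    if isinstance(value, float):
        return round(value, 6)
    if isinstance(value, (list, tuple)):
        return [_round6(v) for v in value]
    return value


def write_result_json(
    result: RowExtractionResult | EvalAggregates,
    path: str | Path,
    homography: Homography | None = None,
) -> None:
    """Serialize an extraction result or evaluation aggregate to JSON."""
    if isinstance(result, RowExtractionResult):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "row_extraction",
            "homography": _round6(homography.as_flat_list()) if homography else None,
            "rows": [
                {
                    "m": round(r.m, 6),
                    "c": round(r.c, 6),
                    "n_points": r.n_points,
                    "fitter": r.fitter.value,
                    "image_segment": _round6(seg.tolist()),
                }
                for r, seg in zip(result.all_rows, result.image_segments)
            ],
            "selected": list(result.selected),
            "noise_count": result.noise_count,
            "timing_ms": {k: round(v, 6) for k, v in result.timing_ms.items()},
        }
    elif isinstance(result, EvalAggregates):
        payload = {
            "schema_version": SCHEMA_VERSION,
            "kind": "evaluation",
            "validity_rate": _round6(result.validity_rate),
            "mean_theta_deg": _round6(result.mean_theta),
            "sd_theta_deg": _round6(result.sd_theta),
            "mean_delta_px": _round6(result.mean_delta),
            "sd_delta_px": _round6(result.sd_delta),
            "mean_time_ms": _round6(result.mean_time_ms),
            "fps": _round6(result.fps),
            "n_images": result.n_images,
            "n_rows": result.n_rows,
        }
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def read_result_json(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if "schema_version" not in data:
        raise LabelFormatError(f"{path}: missing schema_version")
    return data
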