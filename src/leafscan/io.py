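"""Domain types and file formats for scan detections and leaf positions.

A *scan* is a sequence of images taken by a single downward-facing camera
translated in equal steps along a straight line.  Each image yields zero or
more axis-aligned bounding-box detections of leaves.  Pixel coordinates are
0-based with the origin at the top-left corner, x to the right, y down; a
box is anchored at its top-left corner and described by width and height.
The image centre is taken at (image_w/2, image_h/2), i.e. (320, 240) for the
default 640x480 frame, so the half-extents of the frame are exactly
(image_w/2, image_h/2) pixels.

Two detection formats are supported: a COCO-style JSON (``images`` +
``annotations`` with ``bbox`` [x, y, w, h]) extended with a top-level
``scan`` block carrying the scan geometry, and a flat CSV with columns
``image_index, box_x, box_y, box_w, box_h, confidence`` (plus an optional
``detection_id``).  Estimated leaf positions round-trip through JSON or CSV
at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "Detection",
    "ScanSeries",
    "LeafTrack",
    "LeafPosition",
    "DetectionParseError",
    "load_detections",
    "save_detections",
    "load_positions",
    "save_positions",
]

UNASSIGNED = -1

_DETECTION_CSV_COLUMNS = [
    "image_index", "box_x", "box_y", "box_w", "box_h", "confidence",
]
_POSITION_CSV_COLUMNS = [
    "leaf_id", "x_mm", "y_mm", "depth_mm", "n_detections", "residual_px",
]


class DetectionParseError(ValueError):
    """A detection file is malformed; the message names the offending record."""


@dataclass
class Detection:
    """One bounding box in one scan image.

    ``leaf_id`` starts unassigned (-1) and is filled in by the grouping
    algorithm; all other fields come from the detector (or simulator).
    """

    image_index: int
    detection_id: int
    box_x: float
    box_y: float
    box_w: float
    box_h: float
    confidence: float = 1.0
    leaf_id: int = UNASSIGNED

    def __post_init__(self) -> None:
        if self.box_w <= 0 or self.box_h <= 0:
            raise ValueError(
                f"detection {self.detection_id}: box size must be positive, "
                f"got w={self.box_w}, h={self.box_h}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"detection {self.detection_id}: confidence must be in [0, 1], "
                f"got {self.confidence}"
            )
        if self.image_index < 0:
            raise ValueError(
                f"detection {self.detection_id}: negative image_index"
            )

    @property
    def centre_x(self) -> float:
        return self.box_x + self.box_w / 2.0

    @property
    def centre_y(self) -> float:
        return self.box_y + self.box_h / 2.0

    def centre(self, axis: Literal["x", "y"]) -> float:
        return self.centre_x if axis == "x" else self.centre_y

    def size(self, axis: Literal["x", "y"]) -> float:
        return self.box_w if axis == "x" else self.box_h


@dataclass
class ScanSeries:
    """All detections of one linear scan plus the scan geometry.

    ``motion_axis`` names the *image* axis onto which the camera translation
    projects ('x' by default); the transverse axis is the other one.
    ``step_mm`` is the metric camera translation between consecutive images
    (the quantity usually written cx).
    """

    detections: list[Detection]
    n_images: int
    step_mm: float
    image_w: int = 640
    image_h: int = 480
    motion_axis: Literal["x", "y"] = "x"

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.motion_axis not in ("x", "y"):
            raise ValueError("motion_axis must be 'x' or 'y'")
        for d in self.detections:
            if d.image_index >= self.n_images:
                raise ValueError(
                    f"detection {d.detection_id}: image_index {d.image_index} "
                    f">= n_images {self.n_images}"
                )
        ids = [d.detection_id for d in self.detections]
        if len(set(ids)) != len(ids):
            raise ValueError("detection_ids are not unique within the scan")

    @property
    def transverse_axis(self) -> Literal["x", "y"]:
        return "y" if self.motion_axis == "x" else "x"

    def in_image(self, image_index: int) -> list[Detection]:
        return [d for d in self.detections if d.image_index == image_index]

    def copy(self) -> "ScanSeries":
        return replace(self, detections=[replace(d) for d in self.detections])


@dataclass
class LeafTrack:
    """Detections attributed to one leaf, ordered by image index.

    At most one detection per image; depth estimation needs at least two.
    """

    leaf_id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("a track must contain at least one detection")
        idx = [d.image_index for d in self.detections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"track {self.leaf_id}: image indices must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def image_indices(self) -> list[int]:
        return [d.image_index for d in self.detections]

    @property
    def first_image(self) -> int:
        return self.detections[0].image_index

    @property
    def last_image(self) -> int:
        return self.detections[-1].image_index


@dataclass
class LeafPosition:
    """Estimated 3D leaf position in the world frame.

    The world origin sits on the first camera position's optical axis; the
    scan axis is world x, the transverse horizontal axis world y, and
    ``depth_mm`` is the positive distance below the camera plane.
    ``residual_px`` is the RMS residual of the track's motion-axis linear
    fit — a per-leaf dispersion diagnostic.
    """

    leaf_id: int
    x_mm: float
    y_mm: float
    depth_mm: float
    n_detections: int
    residual_px: float

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise ValueError(f"leaf {self.leaf_id}: depth_mm must be positive")
        if self.n_detections < 2:
            raise ValueError(f"leaf {self.leaf_id}: needs >= 2 detections")


# ---------------------------------------------------------------------------
# Detection I/O


def _detection_from_row(i: int, row: dict) -> Detection:
    try:
        return Detection(
            image_index=int(row["image_index"]),
            detection_id=int(row.get("detection_id", i)),
            box_x=float(row["box_x"]),
            box_y=float(row["box_y"]),
            box_w=float(row["box_w"]),
            box_h=float(row["box_h"]),
            confidence=float(row.get("confidence", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise DetectionParseError(f"record {i}: missing/invalid field: {exc}") from exc


def load_detections(
    path: str | Path,
    format: Literal["coco_json", "csv"] | None = None,
    *,
    step_mm: float = 31.25,
    image_w: int = 640,
    image_h: int = 480,
    n_images: int | None = None,
    motion_axis: Literal["x", "y"] = "x",
) -> ScanSeries:
    """Read a detection file into a :class:`ScanSeries`.

    ``format`` defaults from the file suffix.  For CSV (which has no header
    block for geometry) the scan geometry comes from the keyword arguments;
    COCO JSON written by :func:`save_detections` carries it in a ``scan``
    block.  ``n_images`` defaults to max image_index + 1.  All leaf ids come
    back unassigned.
    """
    path = Path(path)
    if format is None:
        format = "coco_json" if path.suffix.lower() == ".json" else "csv"

    if format == "coco_json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise DetectionParseError(f"{path}: not valid JSON: {exc}") from exc
        scan = doc.get("scan", {})
        images = doc.get("images", [])
        if images:
            image_w = int(images[0].get("width", image_w))
            image_h = int(images[0].get("height", image_h))
        step_mm = float(scan.get("step_mm", step_mm))
        motion_axis = scan.get("motion_axis", motion_axis)
        n_images = scan.get("n_images", n_images) or (len(images) or None)
        dets = []
        for i, ann in enumerate(doc.get("annotations", [])):
            try:
                x, y, w, h = ann["bbox"]
            except (KeyError, ValueError, TypeError) as exc:
                raise DetectionParseError(f"annotation {i}: bad bbox: {exc}") from exc
            row = {
                "image_index": ann.get("image_id"),
                "detection_id": ann.get("id", i),
                "box_x": x, "box_y": y, "box_w": w, "box_h": h,
                "confidence": ann.get("score", 1.0),
            }
            dets.append(_detection_from_row(i, row))
    elif format == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in _DETECTION_CSV_COLUMNS[:5] if c not in frame.columns]
        if missing:
            raise DetectionParseError(f"{path}: missing columns {missing}")
        dets = [
            _detection_from_row(i, row)
            for i, row in enumerate(frame.to_dict(orient="records"))
        ]
    else:
        raise ValueError(f"unknown format {format!r}")

    if n_images is None:
        n_images = max((d.image_index for d in dets), default=0) + 1
    return ScanSeries(
        detections=dets,
        n_images=int(n_images),
        step_mm=step_mm,
        image_w=image_w,
        image_h=image_h,
        motion_axis=motion_axis,
    )


def save_detections(
    series: ScanSeries,
    path: str | Path,
    format: Literal["coco_json", "csv"] | None = None,
) -> None:
    """Write a :class:`ScanSeries` to COCO-style JSON or flat CSV."""
    path = Path(path)
    if format is None:
        format = "coco_json" if path.suffix.lower() == ".json" else "csv"

    if format == "coco_json":
        doc = {
            "scan": {
                "n_images": series.n_images,
                "step_mm": series.step_mm,
                "motion_axis": series.motion_axis,
            },
            "images": [
                {"id": i, "file_name": f"scan_{i:03d}.png",
                 "width": series.image_w, "height": series.image_h}
                for i in range(series.n_images)
            ],
            "annotations": [
                {"id": d.detection_id, "image_id": d.image_index,
                 "bbox": [d.box_x, d.box_y, d.box_w, d.box_h],
                 "score": d.confidence, "category_id": 1}
                for d in series.detections
            ],
            "categories": [{"id": 1, "name": "leaf"}],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    elif format == "csv":
        frame = pd.DataFrame(
            [
                {
                    "image_index": d.image_index,
                    "box_x": d.box_x, "box_y": d.box_y,
                    "box_w": d.box_w, "box_h": d.box_h,
                    "confidence": d.confidence,
                    "detection_id": d.detection_id,
                }
                for d in series.detections
            ],
            columns=_DETECTION_CSV_COLUMNS + ["detection_id"],
        )
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Position I/O


def save_positions(
    positions: Iterable[LeafPosition],
    path: str | Path,
    format: Literal["json", "csv"] | None = None,
) -> None:
    """Write estimated positions; round-trips losslessly (repr precision)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    records = [
        {
            "leaf_id": p.leaf_id,
            "x_mm": p.x_mm,
            "y_mm": p.y_mm,
            "depth_mm": p.depth_mm,
            "n_detections": p.n_detections,
            "residual_px": p.residual_px,
        }
        for p in positions
    ]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    elif format == "csv":
        frame = pd.DataFrame(records, columns=_POSITION_CSV_COLUMNS)
        frame.to_csv(path, index=False)  # default str() is shortest round-trip repr
    else:
        raise ValueError(f"unknown format {format!r}")


def load_positions(
    path: str | Path,
    format: Literal["json", "csv"] | None = None,
) -> list[LeafPosition]:
    """Read back a positions file written by :func:`save_positions`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        with open(path) as fh:
            records = json.load(fh)
    elif format == "csv":
        records = pd.read_csv(path).to_dict(orient="records")
    else:
        raise ValueError(f"unknown format {format!r}")
    return [
        LeafPosition(
            leaf_id=int(r["leaf_id"]),
            x_mm=float(r["x_mm"]),
            y_mm=float(r["y_mm"]),
            depth_mm=float(r["depth_mm"]),
            n_detections=int(r["n_detections"]),
            residual_px=float(r["residual_px"]),
        )
        for r in records
    ]
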