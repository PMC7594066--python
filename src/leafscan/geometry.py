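"""Depth from motion parallax and 3D leaf position assembly.

The camera is translated in equal metric steps cx along a straight line.  A
leaf at depth D below the camera drifts across the image by px pixels per
step; depth and per-step pixel separation are related by a calibrated power
law

    D = (px / (a * cx)) ** b,

with a approximately the focal length in pixels and b close to -1 (an ideal
pinhole gives exactly px = f * cx / D).  The calibration constants (a, b)
come from imaging two points a known distance apart at known depths and
fitting the log-log relation by least squares.

Given the depth, the metric offset of an object from the optical axis
follows from its pixel offset pd via the angular model

    Ld = D * tan(asin(pd * sin(phi) / pm)),

where phi is the half field-of-view angle of the image axis and pm the
pixels between image centre and edge.  Combining the two along both image
axes, and adding the known camera position per image, turns a leaf's track
of bounding boxes into a 3D position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grouping import GroupingParams, assign_leaf_ids, postprocess_tracks
from .io import LeafPosition, LeafTrack, ScanSeries

__all__ = [
    "CameraModel",
    "CalibrationTable",
    "default_camera",
    "fit_power_calibration",
    "depth_from_separation",
    "depth_error_sensitivity",
    "pixels_per_step",
    "lateral_offset",
    "estimate_leaf_position",
    "reconstruct",
]


@dataclass(frozen=True)
class CameraModel:
    """Power-law depth calibration plus the angular view model.

    ``a`` (px per unit cx-over-depth ratio, roughly the focal length in
    pixels) and ``b`` (dimensionless, negative) parameterize the depth power
    law; ``phi_x``/``phi_y`` are the half field-of-view angles in radians
    and ``pm_x``/``pm_y`` the half frame extents in pixels (320/240 for
    640x480).
    """

    a: float = 381.0
    b: float = -0.95
    phi_x: float = math.radians(28.0)
    phi_y: float = math.atan(0.75 * math.tan(math.radians(28.0)))
    pm_x: float = 320.0
    pm_y: float = 240.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration coefficient a must be positive")
        if self.b >= 0:
            raise ValueError("calibration exponent b must be negative")
        for phi in (self.phi_x, self.phi_y):
            if not 0 < phi < math.pi / 2:
                raise ValueError("half view angles must lie in (0, pi/2)")
        if self.pm_x <= 0 or self.pm_y <= 0:
            raise ValueError("half frame extents must be positive")

    def phi(self, axis: str) -> float:
        return self.phi_x if axis == "x" else self.phi_y

    def pm(self, axis: str) -> float:
        return self.pm_x if axis == "x" else self.pm_y


def default_camera(
    phi_x_deg: float = 28.0, image_w: int = 640, image_h: int = 480, **kwargs
) -> CameraModel:
    """Camera model with phi_y derived from the aspect ratio.

    The vertical half-angle follows from the horizontal one under a
    rectilinear assumption: tan(phi_y) = (image_h / image_w) * tan(phi_x).
    """
    phi_x = math.radians(phi_x_deg)
    phi_y = math.atan((image_h / image_w) * math.tan(phi_x))
    return CameraModel(
        phi_x=phi_x, phi_y=phi_y,
        pm_x=image_w / 2.0, pm_y=image_h / 2.0,
        **kwargs,
    )


@dataclass
class CalibrationTable:
    """Rows of (known depth, measured pixel separation, metric spacing).

    The metric spacing of the two imaged points stands in for the camera
    step cx: two points s apart seen from one position are geometrically the
    same as one point seen from two positions s apart.
    """

    depth_mm: list[float] = field(default_factory=list)
    separation_px: list[float] = field(default_factory=list)
    spacing_mm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.depth_mm)
        if len(self.separation_px) != n or len(self.spacing_mm) != n:
            raise ValueError("calibration columns must have equal length")
        for col in (self.depth_mm, self.separation_px, self.spacing_mm):
            if any(v <= 0 for v in col):
                raise ValueError("calibration entries must be positive")

    def __len__(self) -> int:
        return len(self.depth_mm)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        frame = pd.read_csv(path)
        return cls(
            depth_mm=frame["depth_mm"].tolist(),
            separation_px=frame["separation_px"].tolist(),
            spacing_mm=frame["spacing_mm"].tolist(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "depth_mm": self.depth_mm,
                "separation_px": self.separation_px,
                "spacing_mm": self.spacing_mm,
            }
        ).to_csv(path, index=False)


def fit_power_calibration(table: CalibrationTable) -> tuple[float, float]:
    """Least-squares fit of the depth power law on a calibration table.

    Fits log(px / cx) = log a + (1/b) * log D by least squares and inverts
    the slope, i.e. the regression runs from the exactly known depths to the
    measured separations — the separations carry the measurement noise, and
    putting them on the regressor side would attenuate the exponent and
    bias ``a`` upward.  On noise-free data this recovers the generating
    (a, b) to numerical precision.  Needs at least two distinct depths.

    Rows are weighted by their separation: pixel noise is additive, so on
    the log scale a 20 px separation is an order of magnitude noisier than
    a 200 px one.
    """
    if len(table) < 2:
        raise ValueError("calibration needs >= 2 rows")
    sep = np.asarray(table.separation_px, dtype=float)
    x = np.log(np.asarray(table.depth_mm, dtype=float))
    y = np.log(sep / np.asarray(table.spacing_mm))
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate calibration: single distinct depth")
    m, c = np.polyfit(x, y, 1, w=sep)
    if m >= 0:
        raise ValueError(
            "calibration fit produced non-negative exponent; separations "
            "must shrink with depth"
        )
    return float(math.exp(c)), float(1.0 / m)


def depth_from_separation(
    px_per_step: float, cx: float, model: CameraModel
) -> float:
    """Depth in mm from per-step pixel separation; strictly decreasing in px."""
    if px_per_step <= 0:
        raise ValueError(
            "non-positive pixel separation: leaf shows no measurable parallax"
        )
    if cx <= 0:
        raise ValueError("camera step cx must be positive")
    return (px_per_step / (model.a * cx)) ** model.b


def separation_from_depth(depth: float, cx: float, model: CameraModel) -> float:
    """Inverse of :func:`depth_from_separation`: px = a * cx * D**(1/b)."""
    if depth <= 0 or cx <= 0:
        raise ValueError("depth and cx must be positive")
    return model.a * cx * depth ** (1.0 / model.b)


def depth_error_sensitivity(
    depth: float, depth_error: float, cx: float, model: CameraModel
) -> float:
    """Pixel-separation change corresponding to a given depth error.

    Returns px(depth) - px(depth + depth_error): the number of pixels by
    which the measured separation would have to be off to move the estimate
    from ``depth`` to ``depth + depth_error``.  Positive for positive
    depth_error (greater depth means less parallax).
    """
    if depth <= 0 or depth + depth_error <= 0:
        raise ValueError("depths must stay positive")
    return separation_from_depth(depth, cx, model) - separation_from_depth(
        depth + depth_error, cx, model
    )


def pixels_per_step(track: LeafTrack, motion_axis: str = "x") -> float:
    """Per-step parallax of a track: |least-squares slope| of the
    motion-axis centre coordinate against image index.

    Equals the mean consecutive separation when no image is missed, and
    normalizes correctly across bridged gaps.
    """
    if len(track) < 2:
        raise ValueError("parallax needs >= 2 detections")
    idx = np.array(track.image_indices, dtype=float)
    c = np.array([d.centre(motion_axis) for d in track.detections])
    slope, _ = np.polyfit(idx, c, 1)
    return float(abs(slope))


def motion_fit_rms(track: LeafTrack, motion_axis: str = "x") -> float:
    """RMS residual of the motion-axis linear fit (dispersion diagnostic)."""
    idx = np.array(track.image_indices, dtype=float)
    c = np.array([d.centre(motion_axis) for d in track.detections])
    coeff = np.polyfit(idx, c, 1)
    return float(np.sqrt(np.mean((c - np.polyval(coeff, idx)) ** 2)))


def lateral_offset(pd: float, depth: float, phi: float, pm: float) -> float:
    """Metric offset from the optical axis given a signed pixel offset.

    Ld = sign(pd) * depth * tan(asin(|pd| * sin(phi) / pm)).  Raises when
    |pd| > pm (object outside the frame).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if abs(pd) > pm:
        raise ValueError(f"pixel offset {pd} outside the frame (pm={pm})")
    return math.copysign(
        depth * math.tan(math.asin(abs(pd) * math.sin(phi) / pm)), pd
    )


def estimate_leaf_position(
    track: LeafTrack, series: ScanSeries, model: CameraModel
) -> LeafPosition:
    """Turn one track into a 3D position.

    Depth comes from the track's per-step parallax through the power law;
    each detection then contributes a world (x, y) as camera position plus
    the angular lateral offsets of its centre, and the reported position is
    the mean.  The world origin is the first camera position's optical axis,
    world x the scan axis.  Centres that noise pushes nominally outside the
    frame are clipped to the frame edge before the arcsin.
    """
    if len(track) < 2:
        raise ValueError("position estimation needs >= 2 detections")
    maxis = series.motion_axis
    taxis = series.transverse_axis
    depth = depth_from_separation(
        pixels_per_step(track, maxis), series.step_mm, model
    )
    centre_m = series.image_w / 2.0 if maxis == "x" else series.image_h / 2.0
    centre_t = series.image_h / 2.0 if maxis == "x" else series.image_w / 2.0

    xs, ys = [], []
    for d in track.detections:
        cam = d.image_index * series.step_mm
        pd_m = _clip(d.centre(maxis) - centre_m, model.pm(maxis))
        pd_t = _clip(d.centre(taxis) - centre_t, model.pm(taxis))
        xs.append(cam + lateral_offset(pd_m, depth, model.phi(maxis), model.pm(maxis)))
        ys.append(lateral_offset(pd_t, depth, model.phi(taxis), model.pm(taxis)))
    return LeafPosition(
        leaf_id=track.leaf_id,
        x_mm=float(np.mean(xs)),
        y_mm=float(np.mean(ys)),
        depth_mm=depth,
        n_detections=len(track),
        residual_px=motion_fit_rms(track, maxis),
    )


def _clip(pd: float, pm: float) -> float:
    return max(-pm, min(pm, pd))


def reconstruct(
    series: ScanSeries,
    params: GroupingParams | None = None,
    model: CameraModel | None = None,
) -> list[LeafPosition]:
    """End-to-end pipeline: group detections, post-process the tracks, and
    estimate one 3D position per surviving track.

    Tracks with no measurable parallax (zero motion-axis slope, e.g. a
    stationary false-positive cluster) are skipped.  Deterministic given its
    inputs.
    """
    params = params or GroupingParams()
    model = model or CameraModel()
    tracks = postprocess_tracks(assign_leaf_ids(series, params), params)
    positions = []
    for t in tracks:
        try:
            positions.append(estimate_leaf_position(t, series, model))
        except ValueError:
            continue
    return positions
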