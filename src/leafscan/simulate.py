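"""Synthetic linear-scan generator standing in for robot, camera and detector.

Leaves are modelled as planar axis-aligned rectangles parallel to the image
plane, at known world position (x along the scan axis, y transverse, depth
below the camera).  Each of N equally spaced camera positions projects every
leaf's four box corners through the angular view model

    pd = pm * sin(atan(L / depth)) / sin(phi)

(the exact inverse of the lateral-offset formula used for reconstruction),
yielding a bounding box per leaf per image.  A noise model then emulates the
detector: Gaussian jitter on the box coordinates, a per-image detection
probability (0.69 by default — the observed chance of re-detecting a leaf in
another image), occlusion-driven misses (a leaf is missed when its projected
centre falls inside a shallower leaf's projected box), and Poisson false
positives with uniform random boxes.  Every emitted detection carries a
ground-truth label so grouping can be scored; false positives get unique
negative labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CalibrationTable, CameraModel, default_camera
from .io import Detection, ScanSeries

__all__ = [
    "SyntheticLeaf",
    "NoiseModel",
    "project_point",
    "render_scan",
    "make_calibration_table",
    "make_artificial_plant",
]


@dataclass(frozen=True)
class SyntheticLeaf:
    """A flat rectangular leaf at a known 3D position (mm)."""

    leaf_id_true: int
    x_mm: float
    y_mm: float
    depth_mm: float
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise ValueError("leaf depth must be positive")
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("leaf extents must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Detector emulation: box jitter, misses, occlusion and clutter.

    ``sigma_px`` is the std. dev. of independent Gaussian noise on each box
    coordinate (x, y, w, h); ``detect_prob`` the per-image probability that
    a visible, unoccluded leaf is detected; ``fp_rate`` the expected number
    of false positives per image.  With ``occlusion`` on, a leaf whose
    projected centre lies inside a shallower leaf's projected box is missed
    in that image.
    """

    sigma_px: float = 0.0
    detect_prob: float = 0.69
    fp_rate: float = 0.0
    occlusion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


NOISELESS = NoiseModel(sigma_px=0.0, detect_prob=1.0, fp_rate=0.0, occlusion=False)


def _pd_from_offset(L: float, depth: float, phi: float, pm: float) -> float:
    """Signed pixel offset of a point L mm off-axis at the given depth."""
    return pm * math.sin(math.atan2(L, depth)) / math.sin(phi)


def project_point(
    world_x: float,
    world_y: float,
    depth: float,
    camera_x: float,
    model: CameraModel,
) -> tuple[float, float] | None:
    """Pixel position of a world point seen from a camera at ``camera_x``.

    The camera sits on the scan axis (world y = 0) looking straight down;
    the scan-direction offset lands on image x.  Returns None when the point
    projects outside the frame (|pd| > pm on either axis).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    pd_x = _pd_from_offset(world_x - camera_x, depth, model.phi_x, model.pm_x)
    pd_y = _pd_from_offset(world_y, depth, model.phi_y, model.pm_y)
    if abs(pd_x) > model.pm_x or abs(pd_y) > model.pm_y:
        return None
    return model.pm_x + pd_x, model.pm_y + pd_y


def _project_box(
    leaf: SyntheticLeaf, camera_x: float, model: CameraModel
) -> tuple[float, float, float, float, bool]:
    """Project a leaf's four corners; returns (x, y, w, h, fully_visible)."""
    lx = leaf.x_mm - camera_x
    x1 = model.pm_x + _pd_from_offset(lx - leaf.width_mm / 2, leaf.depth_mm,
                                      model.phi_x, model.pm_x)
    x2 = model.pm_x + _pd_from_offset(lx + leaf.width_mm / 2, leaf.depth_mm,
                                      model.phi_x, model.pm_x)
    y1 = model.pm_y + _pd_from_offset(leaf.y_mm - leaf.height_mm / 2,
                                      leaf.depth_mm, model.phi_y, model.pm_y)
    y2 = model.pm_y + _pd_from_offset(leaf.y_mm + leaf.height_mm / 2,
                                      leaf.depth_mm, model.phi_y, model.pm_y)
    visible = (
        0.0 <= x1 and x2 <= 2 * model.pm_x and 0.0 <= y1 and y2 <= 2 * model.pm_y
    )
    return x1, y1, x2 - x1, y2 - y1, visible


def leaf_visible(
    leaf: SyntheticLeaf, camera_x: float, model: CameraModel
) -> bool:
    """Whether the whole leaf fits inside the frame from this camera."""
    return _project_box(leaf, camera_x, model)[4]


def render_scan(
    leaves: list[SyntheticLeaf],
    n_images: int,
    step_mm: float,
    model: CameraModel | None = None,
    noise: NoiseModel | None = None,
) -> tuple[ScanSeries, dict[int, int]]:
    """Render a scan into detections plus ground-truth labels.

    Camera i sits at x = i * step_mm.  A leaf is emitted in an image when it
    is fully inside the frame, not occluded, and survives the detection-
    probability draw; its box coordinates then receive independent Gaussian
    noise.  False positives are appended per image with uniform boxes and
    unique negative ground-truth labels.  Fully reproducible from
    ``noise.seed``; one private RNG stream per call.  (The Gaussian draws
    are consumed for every candidate detection whether or not it is kept, so
    two renders differing only in ``sigma_px`` see identical detection
    patterns and identical unit noise — handy for paired noise sweeps.)
    """
    if n_images < 2:
        raise ValueError("a scan needs >= 2 images (parallax)")
    model = model or default_camera()
    noise = noise or NOISELESS
    rng = np.random.default_rng(noise.seed)
    image_w, image_h = int(round(2 * model.pm_x)), int(round(2 * model.pm_y))

    by_depth = sorted(leaves, key=lambda lf: lf.depth_mm)
    detections: list[Detection] = []
    truth: dict[int, int] = {}
    det_id = 0
    fp_label = -1

    for i in range(n_images):
        cam = i * step_mm
        boxes = {lf.leaf_id_true: _project_box(lf, cam, model) for lf in leaves}
        for leaf in leaves:
            x, y, w, h, visible = boxes[leaf.leaf_id_true]
            if not visible:
                continue
            if noise.occlusion and _occluded(leaf, by_depth, boxes):
                continue
            u = rng.random()
            z = rng.standard_normal(4)
            if u >= noise.detect_prob:
                continue
            bx = x + noise.sigma_px * z[0]
            by = y + noise.sigma_px * z[1]
            bw = max(w + noise.sigma_px * z[2], 1.0)
            bh = max(h + noise.sigma_px * z[3], 1.0)
            conf = 0.6 + 0.4 * rng.random()
            detections.append(
                Detection(
                    image_index=i, detection_id=det_id,
                    box_x=bx, box_y=by, box_w=bw, box_h=bh, confidence=conf,
                )
            )
            truth[det_id] = leaf.leaf_id_true
            det_id += 1
        for _ in range(rng.poisson(noise.fp_rate)):
            bw = rng.uniform(20, 120)
            bh = rng.uniform(20, 120)
            bx = rng.uniform(0, image_w - bw)
            by = rng.uniform(0, image_h - bh)
            conf = 0.6 + 0.4 * rng.random()
            detections.append(
                Detection(
                    image_index=i, detection_id=det_id,
                    box_x=bx, box_y=by, box_w=bw, box_h=bh, confidence=conf,
                )
            )
            truth[det_id] = fp_label
            det_id += 1
            fp_label -= 1

    series = ScanSeries(
        detections=detections, n_images=n_images, step_mm=step_mm,
        image_w=image_w, image_h=image_h, motion_axis="x",
    )
    return series, truth


def _occluded(
    leaf: SyntheticLeaf,
    by_depth: list[SyntheticLeaf],
    boxes: dict[int, tuple[float, float, float, float, bool]],
) -> bool:
    x, y, w, h, _ = boxes[leaf.leaf_id_true]
    cx_px, cy_px = x + w / 2, y + h / 2
    for other in by_depth:
        if other.depth_mm >= leaf.depth_mm:
            break  # sorted: no shallower leaves beyond this point
        ox, oy, ow, oh, _ = boxes[other.leaf_id_true]
        if ox <= cx_px <= ox + ow and oy <= cy_px <= oy + oh:
            return True
    return False


def make_calibration_table(
    model: CameraModel | None = None,
    depths: list[float] = (150.0, 200.0, 250.0, 300.0),
    spacings: list[float] = (25.0, 50.0, 100.0),
) -> CalibrationTable:
    """Simulate the two-point calibration procedure.

    For each (depth, spacing) pair, two points ``spacing`` apart are centred
    on the optical axis and projected; the pixel distance between them forms
    one table row.  Pairs whose points fall outside the frame are skipped.
    """
    if not len(depths) or not len(spacings):
        raise ValueError("depths and spacings must be non-empty")
    model = model or default_camera()
    rows_d, rows_sep, rows_s = [], [], []
    for depth in depths:
        for s in spacings:
            pd = _pd_from_offset(s / 2.0, depth, model.phi_x, model.pm_x)
            if pd > model.pm_x:
                continue  # spacing projects outside the frame
            rows_d.append(float(depth))
            rows_sep.append(2.0 * pd)
            rows_s.append(float(s))
    if not rows_d:
        raise ValueError("every calibration pair projected outside the frame")
    return CalibrationTable(
        depth_mm=rows_d, separation_px=rows_sep, spacing_mm=rows_s
    )


def _unoccluded_frames(
    leaf: SyntheticLeaf,
    all_leaves: list[SyntheticLeaf],
    cameras: list[float],
    model: CameraModel,
) -> int:
    """Frames in which the leaf is fully in frame and not occluded."""
    by_depth = sorted(all_leaves, key=lambda lf: lf.depth_mm)
    count = 0
    for cam in cameras:
        boxes = {lf.leaf_id_true: _project_box(lf, cam, model) for lf in all_leaves}
        if boxes[leaf.leaf_id_true][4] and not _occluded(leaf, by_depth, boxes):
            count += 1
    return count


def make_artificial_plant(
    n_leaves: int = 18,
    length_range_mm: tuple[float, float] = (55.0, 115.0),
    height_range_mm: tuple[float, float] = (90.0, 340.0),
    seed: int = 0,
    *,
    n_images: int = 9,
    step_mm: float = 31.25,
    model: CameraModel | None = None,
    scan_width_mm: float = 250.0,
    aspect_range: tuple[float, float] = (0.5, 0.9),
    min_visible: int = 2,
) -> list[SyntheticLeaf]:
    """Random dense artificial plant for stress-testing the grouping.

    Leaf lengths are uniform over ``length_range_mm`` (the second planar
    extent is a random fraction of the length), depths uniform over
    ``height_range_mm`` below the camera, and horizontal positions uniform
    over the scannable area.  Size, depth and position are rejection-sampled
    jointly until the leaf (a) is fully inside the frame in at least
    ``min_visible`` scan images and (b) is unoccluded in at least one image
    without fully hiding any leaf already placed.  This mirrors how such a
    reference plant is built and labelled: only leaves visible somewhere in
    the scan exist as labels at all (a 115 mm leaf 90 mm under the camera
    can never fit the frame, and a leaf under cover in every image cannot be
    labelled), while leaves visible in only one or two images remain — those
    are exactly the ones the pipeline may fail to localize.  Reproducible
    from ``seed``.
    """
    if length_range_mm[0] <= 0 or height_range_mm[0] <= 0:
        raise ValueError("ranges must be positive")
    model = model or default_camera()
    rng = np.random.default_rng(seed)
    cameras = [i * step_mm for i in range(n_images)]
    leaves: list[SyntheticLeaf] = []
    for leaf_id in range(n_leaves):
        for _ in range(10_000):
            length = rng.uniform(*length_range_mm)
            other = length * rng.uniform(*aspect_range)
            depth = rng.uniform(*height_range_mm)
            x = rng.uniform(0.0, scan_width_mm)
            y = rng.uniform(-scan_width_mm / 2.0, scan_width_mm / 2.0)
            leaf = SyntheticLeaf(
                leaf_id_true=leaf_id, x_mm=x, y_mm=y, depth_mm=depth,
                width_mm=length, height_mm=other,
            )
            n_vis = sum(leaf_visible(leaf, cam, model) for cam in cameras)
            if n_vis < min_visible:
                continue
            trial = leaves + [leaf]
            if _unoccluded_frames(leaf, trial, cameras, model) < 1:
                continue
            if any(
                _unoccluded_frames(prev, trial, cameras, model) < 1
                for prev in leaves
            ):
                continue
            leaves.append(leaf)
            break
        else:  # pragma: no cover - bounds are generous for sane configs
            raise RuntimeError("could not place a visible leaf")
    return leaves
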