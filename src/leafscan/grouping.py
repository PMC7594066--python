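"""Unsupervised grouping of leaf detections across a linear scan.

Detections of the same leaf in consecutive images are linked greedily with a
match probability

    P = 1 / (ks * Bs + kp * Bp)

where Bs is the summed absolute difference of box width and height between
the two detections and Bp the absolute difference of their centre position
on the axis *transverse* to the camera motion.  Because the camera moves in
a straight line, a leaf's image drifts along the motion axis (that drift is
the parallax signal) while its transverse position stays put — so only the
transverse offset counts as mismatch.  A pair is accepted when P exceeds a
threshold; larger P is equivalent to a smaller denominator, and comparisons
are done on the denominator so the perfect-match case (Bs = Bp = 0,
P infinite) needs no special float handling.

A post-processing pass then (1) removes detections that sit far off their
track's straight-line motion fit, (2) bridges tracks split by missed
detections via linear extrapolation, and (3) discards tracks too short to
support a depth estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Detection, LeafTrack, ScanSeries

__all__ = [
    "GroupingParams",
    "MatchScore",
    "GroupingMetrics",
    "match_probability",
    "assign_leaf_ids",
    "resolve_duplicates",
    "postprocess_tracks",
    "tracks_from_series",
    "evaluate_grouping",
]


@dataclass(frozen=True)
class GroupingParams:
    """Gains, threshold and post-processing tolerances for grouping.

    ks, kp are the per-pixel gains weighting size and transverse-position
    mismatch.  With the defaults ks = kp = 1 and p_threshold = 1/60, a pair
    is accepted when its combined mismatch is under 60 px on a 640x480
    frame.  max_gap bounds how many consecutive missed images bridging will
    span; merge_tol_px / outlier_tol_px are the extrapolation and residual
    tolerances of post-processing; tracks shorter than min_track_len are
    dropped (a depth estimate needs at least two views).
    """

    ks: float = 1.0
    kp: float = 1.0
    p_threshold: float = 1.0 / 60.0
    max_gap: int = 2
    merge_tol_px: float = 15.0
    outlier_tol_px: float = 15.0
    min_track_len: int = 2

    def __post_init__(self) -> None:
        if self.ks < 0 or self.kp < 0 or self.ks + self.kp <= 0:
            raise ValueError("gains must be non-negative with ks + kp > 0")
        if self.p_threshold <= 0:
            raise ValueError("p_threshold must be positive")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.min_track_len < 2:
            raise ValueError("min_track_len must be >= 2")

    @property
    def denominator_threshold(self) -> float:
        """Mismatch bound equivalent to p_threshold: accept iff denom < this."""
        return 1.0 / self.p_threshold


@dataclass(frozen=True)
class MatchScore:
    """Match probability between two detections plus its components."""

    bs: float
    bp: float
    denominator: float
    p: float

    def __lt__(self, other: "MatchScore") -> bool:
        # better score == smaller denominator; ordering by p would need
        # special-casing the infinite perfect match
        return self.denominator < other.denominator


def match_probability(
    d1: Detection,
    d2: Detection,
    params: GroupingParams,
    transverse_axis: str = "y",
) -> MatchScore:
    """Score a pair of detections from any two images.

    Symmetric in its arguments.  Identical boxes give an infinite
    probability (zero mismatch).
    """
    bs = abs(d1.box_w - d2.box_w) + abs(d1.box_h - d2.box_h)
    bp = abs(d1.centre(transverse_axis) - d2.centre(transverse_axis))
    denom = params.ks * bs + params.kp * bp
    p = math.inf if denom == 0 else 1.0 / denom
    return MatchScore(bs=bs, bp=bp, denominator=denom, p=p)


def resolve_duplicates(
    claimants: list[Detection],
    prior: Detection,
    params: GroupingParams,
    transverse_axis: str,
    next_id: int,
) -> int:
    """Keep the leaf id on the claimant best matching the track's most
    recent prior detection; give every other claimant a fresh id.

    Ties in score are broken toward the lower detection_id.  Returns the
    next unused fresh id.
    """
    if len(claimants) < 2:
        return next_id
    ranked = sorted(
        claimants,
        key=lambda d: (
            match_probability(d, prior, params, transverse_axis).denominator,
            d.detection_id,
        ),
    )
    for loser in ranked[1:]:
        loser.leaf_id = next_id
        next_id += 1
    return next_id


def assign_leaf_ids(series: ScanSeries, params: GroupingParams | None = None) -> list[LeafTrack]:
    """Greedy consecutive-image assignment of leaf ids (first stage).

    Every detection in the first image seeds a fresh leaf id (one leaf
    cannot appear twice in one image).  Each detection of image k then
    inherits the id of its best-scoring match among image k-1's detections
    iff that score clears the threshold, and otherwise starts a new track.
    Within each image, duplicate claims on one id are resolved against the
    track's most recent prior detection.  Operates on a copy; the input
    series is left untouched.
    """
    params = params or GroupingParams()
    series = series.copy()
    taxis = series.transverse_axis
    next_id = 0

    by_image: list[list[Detection]] = [[] for _ in range(series.n_images)]
    for d in series.detections:
        by_image[d.image_index].append(d)
    for dets in by_image:
        dets.sort(key=lambda d: d.detection_id)

    for d in by_image[0] if by_image else []:
        d.leaf_id = next_id
        next_id += 1

    for k in range(1, series.n_images):
        prev = by_image[k - 1]
        for d in by_image[k]:
            best: Detection | None = None
            best_score: MatchScore | None = None
            for q in prev:
                score = match_probability(d, q, params, taxis)
                if best_score is None or score < best_score:
                    best, best_score = q, score
            if (
                best is not None
                and best_score.denominator < params.denominator_threshold
            ):
                d.leaf_id = best.leaf_id
            else:
                d.leaf_id = next_id
                next_id += 1
        # same-image duplicate check: one leaf cannot appear twice
        claims: dict[int, list[Detection]] = {}
        for d in by_image[k]:
            claims.setdefault(d.leaf_id, []).append(d)
        for leaf_id, claimants in claims.items():
            if len(claimants) < 2:
                continue
            prior = _most_recent(by_image[:k], leaf_id)
            if prior is None:  # fresh ids are unique by construction
                continue
            next_id = resolve_duplicates(claimants, prior, params, taxis, next_id)

    return tracks_from_series(series)


def _most_recent(images: list[list[Detection]], leaf_id: int) -> Detection | None:
    for dets in reversed(images):
        for d in dets:
            if d.leaf_id == leaf_id:
                return d
    return None


def tracks_from_series(series: ScanSeries) -> list[LeafTrack]:
    """Collect assigned detections into LeafTracks, ordered by leaf id."""
    groups: dict[int, list[Detection]] = {}
    for d in series.detections:
        if d.leaf_id < 0:
            raise ValueError(f"detection {d.detection_id} has no leaf id")
        groups.setdefault(d.leaf_id, []).append(d)
    tracks = []
    for leaf_id in sorted(groups):
        dets = sorted(groups[leaf_id], key=lambda d: d.image_index)
        tracks.append(LeafTrack(leaf_id=leaf_id, detections=dets))
    return tracks


# ---------------------------------------------------------------------------
# Post-processing


def _linear_fit(track: LeafTrack) -> tuple[np.ndarray, np.ndarray]:
    """Fit centre (x, y) ~ image_index; returns coeffs ((slope, icept) per axis)."""
    idx = np.array(track.image_indices, dtype=float)
    cx = np.array([d.centre_x for d in track.detections])
    cy = np.array([d.centre_y for d in track.detections])
    deg = 1 if len(track) >= 2 else 0
    fx = np.polyfit(idx, cx, deg)
    fy = np.polyfit(idx, cy, deg)
    return fx, fy


def _residuals(track: LeafTrack) -> np.ndarray:
    fx, fy = _linear_fit(track)
    idx = np.array(track.image_indices, dtype=float)
    rx = np.array([d.centre_x for d in track.detections]) - np.polyval(fx, idx)
    ry = np.array([d.centre_y for d in track.detections]) - np.polyval(fy, idx)
    return np.hypot(rx, ry)


def _remove_outliers(track: LeafTrack, tol_px: float) -> LeafTrack:
    dets = list(track.detections)
    while len(dets) >= 3:
        t = LeafTrack(track.leaf_id, dets)
        res = _residuals(t)
        worst = int(np.argmax(res))
        if res[worst] <= tol_px:
            break
        dets = dets[:worst] + dets[worst + 1:]
    return LeafTrack(track.leaf_id, dets)


def _extrapolation_distance(
    earlier: LeafTrack, later: LeafTrack
) -> float | None:
    """Distance between one track's linear fit extrapolated to the other's
    nearest endpoint and the detection actually there.

    Prefers fitting the earlier track; falls back to extrapolating the later
    track backwards when the earlier one is a singleton.  None when neither
    side has the two detections a line needs.
    """
    if len(earlier) >= 2:
        src, target = earlier, later.detections[0]
    elif len(later) >= 2:
        src, target = later, earlier.detections[-1]
    else:
        return None
    fx, fy = _linear_fit(src)
    px = np.polyval(fx, target.image_index)
    py = np.polyval(fy, target.image_index)
    return float(math.hypot(px - target.centre_x, py - target.centre_y))


def _mean_size_mismatch(t1: LeafTrack, t2: LeafTrack) -> float:
    w1 = float(np.mean([d.box_w for d in t1.detections]))
    h1 = float(np.mean([d.box_h for d in t1.detections]))
    w2 = float(np.mean([d.box_w for d in t2.detections]))
    h2 = float(np.mean([d.box_h for d in t2.detections]))
    return abs(w1 - w2) + abs(h1 - h2)


def postprocess_tracks(
    tracks: list[LeafTrack], params: GroupingParams | None = None
) -> list[LeafTrack]:
    """Outlier removal, gap bridging, and short-track filtering.

    1. Per track with >= 3 detections, iteratively refit the straight-line
       centre motion and drop the worst detection while its (Euclidean)
       residual exceeds ``outlier_tol_px``.
    2. Merge pairs of tracks with disjoint image ranges separated by at most
       ``max_gap`` missing images when the linear fit of one, extrapolated
       to the other's nearest image, lands within ``merge_tol_px`` of the
       detection centre there and the mean box-size difference stays within
       the size mismatch admitted by ``p_threshold``.  Candidate pairs are
       taken in order of increasing extrapolation distance and merging
       repeats to a fixed point.
    3. Drop tracks shorter than ``min_track_len``.
    """
    params = params or GroupingParams()
    tracks = [_remove_outliers(t, params.outlier_tol_px) for t in tracks]

    # size gate: the bs a pair could carry and still clear the threshold
    size_tol = (
        params.denominator_threshold / params.ks if params.ks > 0 else math.inf
    )

    merged = True
    while merged:
        merged = False
        candidates: list[tuple[float, int, int]] = []
        for i, t1 in enumerate(tracks):
            for j, t2 in enumerate(tracks):
                if i == j:
                    continue
                if t1.last_image >= t2.first_image:
                    continue  # need disjoint, ordered ranges
                n_missing = t2.first_image - t1.last_image - 1
                if n_missing > params.max_gap:
                    continue
                if _mean_size_mismatch(t1, t2) > size_tol:
                    continue
                dist = _extrapolation_distance(t1, t2)
                if dist is None or dist > params.merge_tol_px:
                    continue
                candidates.append((dist, i, j))
        if candidates:
            _, i, j = min(candidates)
            keep, absorb = tracks[i], tracks[j]
            fused = LeafTrack(
                keep.leaf_id,
                sorted(
                    keep.detections + absorb.detections,
                    key=lambda d: d.image_index,
                ),
            )
            for d in fused.detections:
                d.leaf_id = keep.leaf_id
            tracks = [t for k, t in enumerate(tracks) if k not in (i, j)]
            tracks.append(fused)
            tracks.sort(key=lambda t: t.leaf_id)
            merged = True

    return [t for t in tracks if len(t) >= params.min_track_len]


# ---------------------------------------------------------------------------
# Evaluation against simulator ground truth


@dataclass(frozen=True)
class GroupingMetrics:
    """Pairwise clustering scores of a grouping against ground truth."""

    pairwise_precision: float
    pairwise_recall: float
    n_true_leaves: int
    n_recovered: int


def _usable_majority(track: LeafTrack, truth: dict[int, int]) -> int | None:
    """True leaf recovered by this track, or None.

    Requires >= 2 detections of one true leaf forming a strict plurality
    (false positives carry unique negative labels and never qualify).
    """
    counts: dict[int, int] = {}
    for d in track.detections:
        label = truth[d.detection_id]
        counts[label] = counts.get(label, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    label, top = ranked[0]
    if label < 0 or top < 2:
        return None
    if len(ranked) > 1 and ranked[1][1] == top:
        return None
    return label


def evaluate_grouping(
    tracks: list[LeafTrack], ground_truth: dict[int, int]
) -> GroupingMetrics:
    """Score a grouping against the simulator's detection -> leaf labels.

    Precision/recall are over unordered same-track detection pairs (a pair
    is correct when both members carry the same non-negative true label).
    ``n_recovered`` counts distinct true leaves owning a usable track: one
    with at least two detections whose plurality label is that leaf.  False
    positives must be labelled with unique negative ids so that they form
    no true pairs.  Raises if a grouped detection is missing from the map.
    """
    for t in tracks:
        for d in t.detections:
            if d.detection_id not in ground_truth:
                raise ValueError(
                    f"ground truth missing detection {d.detection_id}"
                )

    tp = 0
    predicted = 0
    for t in tracks:
        labels = [ground_truth[d.detection_id] for d in t.detections]
        predicted += len(labels) * (len(labels) - 1) // 2
        counts: dict[int, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        tp += sum(c * (c - 1) // 2 for lab, c in counts.items() if lab >= 0)

    truth_counts: dict[int, int] = {}
    for lab in ground_truth.values():
        if lab >= 0:
            truth_counts[lab] = truth_counts.get(lab, 0) + 1
    actual = sum(c * (c - 1) // 2 for c in truth_counts.values())

    recovered = {
        lab
        for t in tracks
        if len(t) >= 2 and (lab := _usable_majority(t, ground_truth)) is not None
    }
    return GroupingMetrics(
        pairwise_precision=tp / predicted if predicted else 1.0,
        pairwise_recall=tp / actual if actual else 1.0,
        n_true_leaves=len(truth_counts),
        n_recovered=len(recovered),
    )
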