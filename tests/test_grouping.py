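"""The greedy match-probability grouping and its post-processing."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafscan.grouping import (
    GroupingParams,
    assign_leaf_ids,
    evaluate_grouping,
    match_probability,
    postprocess_tracks,
    tracks_from_series,
)
from leafscan.io import Detection, LeafTrack, ScanSeries

PARAMS = GroupingParams()  # ks = kp = 1, threshold 1/60


def det(img, det_id, cx, cy, w, h):
    """Detection built from its centre (the grouping works on centres)."""
    return Detection(img, det_id, cx - w / 2, cy - h / 2, w, h)


def series(dets, n_images, **kw):
    kw.setdefault("step_mm", 31.25)
    return ScanSeries(detections=dets, n_images=n_images, **kw)


box = st.tuples(
    st.floats(0, 600, allow_nan=False), st.floats(0, 440, allow_nan=False),
    st.floats(1, 300, allow_nan=False), st.floats(1, 300, allow_nan=False),
)


class TestMatchProbability:
    def test_identical_boxes_match_perfectly(self):
        d1 = det(0, 0, 100, 200, 50, 30)
        d2 = det(1, 1, 100, 200, 50, 30)
        score = match_probability(d1, d2, PARAMS)
        assert score.bs == 0 and score.bp == 0
        assert math.isinf(score.p)

    def test_hand_worked_score(self):
        # sizes 100x50 vs 110x45 -> Bs = 15; transverse (y) centres 200 vs
        # 210 -> Bp = 10; with unit gains P = 1/25
        d1 = det(0, 0, 320, 200, 100, 50)
        d2 = det(1, 1, 250, 210, 110, 45)
        score = match_probability(d1, d2, PARAMS)
        assert score.bs == pytest.approx(15)
        assert score.bp == pytest.approx(10)
        assert score.p == pytest.approx(1 / 25)

    def test_motion_axis_displacement_is_free(self):
        # identical boxes far apart along the motion axis still match
        # perfectly: that displacement is the parallax signal
        d1 = det(0, 0, 100, 200, 50, 30)
        d2 = det(1, 1, 400, 200, 50, 30)
        assert math.isinf(match_probability(d1, d2, PARAMS).p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(box, box)
    def test_symmetry(self, b1, b2):
        d1 = Detection(0, 0, *b1)
        d2 = Detection(1, 1, *b2)
        s12 = match_probability(d1, d2, PARAMS)
        s21 = match_probability(d2, d1, PARAMS)
        assert s12.denominator == s21.denominator

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(box, box, st.floats(-200, 200), st.floats(-200, 200))
    def test_translation_invariance(self, b1, b2, dx, dy):
        # a common shift of both boxes changes nothing; a motion-axis shift
        # of one box alone changes nothing either (bp is transverse-only)
        d1 = Detection(0, 0, *b1)
        d2 = Detection(1, 1, *b2)
        base = match_probability(d1, d2, PARAMS).denominator
        s1 = Detection(0, 0, b1[0] + dx, b1[1] + dy, b1[2], b1[3])
        s2 = Detection(1, 1, b2[0] + dx, b2[1] + dy, b2[2], b2[3])
        assert match_probability(s1, s2, PARAMS).denominator == pytest.approx(base)
        m2 = Detection(1, 1, b2[0] + dx, b2[1], b2[2], b2[3])
        assert match_probability(d1, m2, PARAMS).denominator == pytest.approx(base)


class TestAssignLeafIds:
    def test_first_image_gets_distinct_ids(self):
        s = series([det(0, i, 100 + 200 * i, 200, 50, 50) for i in range(3)], 1)
        tracks = assign_leaf_ids(s, PARAMS)
        assert len(tracks) == 3
        assert sorted(t.leaf_id for t in tracks) == [0, 1, 2]

    def test_two_leaves_followed_across_two_images(self):
        # A/A': transverse centres 100 / 101, same size -> p = 1
        # B/B': centres 300 / 299, sizes 50x50 vs 48x52 -> p = 1/5
        s = series(
            [
                det(0, 0, 320, 100, 50, 50), det(0, 1, 320, 300, 50, 50),
                det(1, 2, 350, 101, 50, 50), det(1, 3, 350, 299, 48, 52),
            ],
            2,
        )
        tracks = assign_leaf_ids(s, PARAMS)
        assert len(tracks) == 2
        grouped = {
            frozenset(d.detection_id for d in t.detections) for t in tracks
        }
        assert grouped == {frozenset({0, 2}), frozenset({1, 3})}

    def test_below_threshold_starts_new_track(self):
        # best p = 1/200 < 1/60 -> fresh id
        s = series(
            [det(0, 0, 320, 100, 50, 50), det(1, 1, 320, 300, 50, 50)], 2
        )
        tracks = assign_leaf_ids(s, PARAMS)
        assert len(tracks) == 2

    def test_duplicate_claim_resolved_by_prior_match(self):
        # both second-image detections best-match detection 0; the closer
        # one keeps the id, the other gets a fresh one
        s = series(
            [
                det(0, 0, 320, 200, 50, 50),
                det(1, 1, 320, 202, 50, 50),   # p = 1/2 vs prior
                det(1, 2, 320, 220, 50, 50),   # p = 1/20 vs prior
            ],
            2,
        )
        tracks = assign_leaf_ids(s, PARAMS)
        winner = next(t for t in tracks if 0 in [d.detection_id for d in t.detections])
        assert [d.detection_id for d in winner.detections] == [0, 1]
        assert len(tracks) == 2

    def test_duplicate_tie_breaks_to_lower_detection_id(self):
        s = series(
            [
                det(0, 0, 320, 200, 50, 50),
                det(1, 1, 320, 210, 50, 50),
                det(1, 2, 320, 190, 50, 50),  # same |offset|, higher id
            ],
            2,
        )
        tracks = assign_leaf_ids(s, PARAMS)
        winner = next(t for t in tracks if t.first_image == 0)
        assert [d.detection_id for d in winner.detections] == [0, 1]

    def test_empty_series_gives_no_tracks(self):
        assert assign_leaf_ids(series([], 3), PARAMS) == []

    def test_assignment_partitions_detections(self):
        dets = [det(i, 3 * i + j, 100 + 40 * i, 100 + 120 * j, 50, 50)
                for i in range(4) for j in range(3)]
        tracks = assign_leaf_ids(series(dets, 4), PARAMS)
        seen = [d.detection_id for t in tracks for d in t.detections]
        assert sorted(seen) == sorted(d.detection_id for d in dets)

    def test_order_within_image_does_not_matter(self):
        dets = [det(i, 3 * i + j, 100 + 40 * i, 100 + 120 * j, 50 + j, 50)
                for i in range(3) for j in range(3)]
        base = {
            frozenset(d.detection_id for d in t.detections)
            for t in assign_leaf_ids(series(dets, 3), PARAMS)
        }
        for perm in itertools.permutations(range(3)):
            shuffled = [det(i, 3 * i + j, 100 + 40 * i, 100 + 120 * j, 50 + j, 50)
                        for i in range(3) for j in perm]
            got = {
                frozenset(d.detection_id for d in t.detections)
                for t in assign_leaf_ids(series(shuffled, 3), PARAMS)
            }
            assert got == base


class TestPostprocess:
    def test_gap_bridging_merges_split_track(self):
        # motion-axis centres 100,150,200 in images 0-2 then 300,350 in 4-5:
        # the earlier fit extrapolates to exactly 300 at image 4
        a = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in range(3)]
        b = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in (4, 5)]
        tracks = [LeafTrack(0, a), LeafTrack(1, b)]
        out = postprocess_tracks(tracks, PARAMS)
        assert len(out) == 1
        assert out[0].image_indices == [0, 1, 2, 4, 5]

    def test_gap_beyond_max_gap_not_bridged(self):
        a = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in range(2)]
        b = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in (6, 7)]
        out = postprocess_tracks([LeafTrack(0, a), LeafTrack(1, b)], PARAMS)
        assert len(out) == 2

    def test_size_gate_blocks_merging_different_leaves(self):
        a = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in range(3)]
        b = [det(i, i, 100 + 50 * i, 200, 150, 90) for i in (4, 5)]
        out = postprocess_tracks([LeafTrack(0, a), LeafTrack(1, b)], PARAMS)
        assert len(out) == 2

    def test_outlier_removed_from_linear_motion(self):
        dets = [det(i, i, 100 + 50 * i, 200, 60, 40) for i in range(4)]
        dets[2] = det(2, 2, 100 + 50 * 2 + 30, 200, 60, 40)  # 30 px off line
        out = postprocess_tracks([LeafTrack(0, dets)],
                                 GroupingParams(outlier_tol_px=10))
        assert len(out) == 1
        assert [d.detection_id for d in out[0].detections] == [0, 1, 3]

    def test_short_tracks_dropped(self):
        tracks = [LeafTrack(i, [det(i, i, 100, 100, 50, 50)]) for i in range(3)]
        assert postprocess_tracks(tracks, PARAMS) == []


class TestEvaluate:
    @staticmethod
    def pairwise_by_enumeration(tracks, truth):
        """Brute-force oracle: enumerate all detection pairs."""
        dets = [(t.leaf_id, d.detection_id) for t in tracks for d in t.detections]
        tp = pred = act = 0
        for (ta, a), (tb, b) in itertools.combinations(dets, 2):
            same_pred = ta == tb
            same_true = truth[a] == truth[b] and truth[a] >= 0
            pred += same_pred
            act += same_true
            tp += same_pred and same_true
        return tp / pred if pred else 1.0, tp / act if act else 1.0

    def make_two_leaf_tracks(self, swap=False):
        rows = []
        for leaf, cy in ((0, 100), (1, 300)):
            for img in range(3):
                rows.append(det(img, 10 * leaf + img, 100 + 40 * img, cy, 50, 50))
        truth = {10 * leaf + img: leaf for leaf in (0, 1) for img in range(3)}
        t0 = [r for r in rows if r.detection_id < 10]
        t1 = [r for r in rows if r.detection_id >= 10]
        if swap:  # exchange the image-2 detections between the tracks
            t0[2], t1[2] = t1[2], t0[2]
            t0.sort(key=lambda d: d.image_index)
            t1.sort(key=lambda d: d.image_index)
        return [LeafTrack(0, t0), LeafTrack(1, t1)], truth

    def test_perfect_partition_scores_one(self):
        tracks, truth = self.make_two_leaf_tracks()
        m = evaluate_grouping(tracks, truth)
        assert m.pairwise_precision == 1.0 and m.pairwise_recall == 1.0
        assert m.n_true_leaves == 2 and m.n_recovered == 2

    def test_singletons_recall_zero(self):
        tracks, truth = self.make_two_leaf_tracks()
        singles = [LeafTrack(i, [d]) for i, d in enumerate(
            d for t in tracks for d in t.detections)]
        m = evaluate_grouping(singles, truth)
        assert m.pairwise_recall == 0.0 and m.n_recovered == 0

    def test_one_swapped_detection_scores_one_third(self):
        tracks, truth = self.make_two_leaf_tracks(swap=True)
        m = evaluate_grouping(tracks, truth)
        oracle_p, oracle_r = self.pairwise_by_enumeration(tracks, truth)
        assert m.pairwise_precision == pytest.approx(oracle_p) == pytest.approx(1 / 3)
        assert m.pairwise_recall == pytest.approx(oracle_r) == pytest.approx(1 / 3)

    def test_missing_ground_truth_raises(self):
        tracks, truth = self.make_two_leaf_tracks()
        truth.pop(11)
        with pytest.raises(ValueError):
            evaluate_grouping(tracks, truth)
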