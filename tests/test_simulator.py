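"""Projection model, scan rendering, calibration bench, artificial plant."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafscan.geometry import lateral_offset, reconstruct
from leafscan.grouping import GroupingParams
from leafscan.simulate import (
    NoiseModel,
    SyntheticLeaf,
    leaf_visible,
    make_artificial_plant,
    make_calibration_table,
    project_point,
    render_scan,
)

NOISE_OFF = NoiseModel(sigma_px=0.0, detect_prob=1.0, fp_rate=0.0,
                       occlusion=False, seed=0)


def central_leaf(leaf_id=0, x=100.0, y=0.0, depth=200.0, w=50.0, h=40.0):
    return SyntheticLeaf(leaf_id, x, y, depth, w, h)


class TestProjection:
    def test_on_axis_point_hits_image_centre(self, geometric_camera):
        px = project_point(100.0, 0.0, 200.0, 100.0, geometric_camera)
        assert px == pytest.approx((320.0, 240.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-60, 60), st.floats(-50, 50), st.floats(120, 400))
    def test_projection_inverts_lateral_offset(self, lx, ly, depth):
        from leafscan.geometry import default_camera

        model = default_camera()
        out = project_point(lx, ly, depth, 0.0, model)
        if out is None:
            return
        px, py = out
        assert lateral_offset(px - 320.0, depth, model.phi_x, model.pm_x) == \
            pytest.approx(lx, abs=1e-9)
        assert lateral_offset(py - 240.0, depth, model.phi_y, model.pm_y) == \
            pytest.approx(ly, abs=1e-9)

    def test_full_view_angle_lands_on_frame_edge(self, geometric_camera):
        depth = 200.0
        lx = depth * math.tan(geometric_camera.phi_x)
        out = project_point(lx, 0.0, depth, 0.0, geometric_camera)
        assert out is not None
        assert out[0] == pytest.approx(640.0, rel=1e-12)

    def test_beyond_frame_is_out(self, geometric_camera):
        depth = 200.0
        lx = depth * math.tan(geometric_camera.phi_x) * 1.01
        assert project_point(lx, 0.0, depth, 0.0, geometric_camera) is None


class TestRenderScan:
    def test_noise_free_central_leaf_seen_once_per_image(self, geometric_camera):
        series, truth = render_scan(
            [central_leaf(x=25.0)], 6, 10.0, geometric_camera, NOISE_OFF
        )
        assert len(series.detections) == 6
        assert sorted(d.image_index for d in series.detections) == list(range(6))
        assert set(truth.values()) == {0}
        # centres drift linearly enough to sit on one line: over this short
        # small-angle traverse the projection's curvature stays sub-pixel
        idx = np.array([d.image_index for d in series.detections], float)
        cx = np.array([d.centre_x for d in series.detections])
        resid = cx - np.polyval(np.polyfit(idx, cx, 1), idx)
        assert np.max(np.abs(resid)) < 1.0

    def test_same_seed_reproduces_different_seed_varies(self, geometric_camera):
        noise = NoiseModel(sigma_px=3.0, detect_prob=0.8, fp_rate=0.5,
                           occlusion=False, seed=42)
        s1, t1 = render_scan([central_leaf(x=75.0)], 6, 30.0, geometric_camera, noise)
        s2, t2 = render_scan([central_leaf(x=75.0)], 6, 30.0, geometric_camera, noise)
        assert t1 == t2
        assert [(d.box_x, d.box_y) for d in s1.detections] == \
               [(d.box_x, d.box_y) for d in s2.detections]
        other = NoiseModel(sigma_px=3.0, detect_prob=0.8, fp_rate=0.5,
                           occlusion=False, seed=43)
        s3, _ = render_scan([central_leaf(x=75.0)], 6, 30.0, geometric_camera, other)
        assert [(d.box_x, d.box_y) for d in s3.detections] != \
               [(d.box_x, d.box_y) for d in s1.detections]

    def test_shallower_leaf_drifts_faster(self, geometric_camera):
        near = central_leaf(0, x=25.0, y=-20.0, depth=150.0, h=30.0)
        far = central_leaf(1, x=25.0, y=20.0, depth=300.0, h=30.0)
        series, truth = render_scan([near, far], 6, 10.0, geometric_camera, NOISE_OFF)
        assert len(series.detections) == 12
        drift = {}
        for leaf_id in (0, 1):
            cx = [d.centre_x for d in series.detections
                  if truth[d.detection_id] == leaf_id]
            drift[leaf_id] = abs(cx[-1] - cx[0]) / (len(cx) - 1)
        assert drift[0] > drift[1]

    def test_occluded_centre_suppressed(self, geometric_camera):
        # a big shallow leaf exactly over a deep one: the deep leaf's centre
        # projects inside the shallow box in every image
        top = central_leaf(0, x=75.0, depth=150.0, w=90.0, h=70.0)
        below = central_leaf(1, x=75.0, depth=300.0, w=40.0, h=30.0)
        noise = NoiseModel(sigma_px=0.0, detect_prob=1.0, occlusion=True, seed=0)
        series, truth = render_scan([top, below], 6, 20.0, geometric_camera, noise)
        assert set(truth.values()) == {0}

    def test_false_positives_labelled_uniquely_negative(self, geometric_camera):
        noise = NoiseModel(sigma_px=0.0, detect_prob=1.0, fp_rate=2.0,
                           occlusion=False, seed=7)
        _, truth = render_scan([central_leaf(x=75.0)], 6, 30.0,
                               geometric_camera, noise)
        negatives = [v for v in truth.values() if v < 0]
        assert negatives and len(set(negatives)) == len(negatives)

    def test_single_image_scan_rejected(self, geometric_camera):
        with pytest.raises(ValueError):
            render_scan([central_leaf()], 1, 30.0, geometric_camera, NOISE_OFF)


class TestCalibrationBench:
    def test_separation_matches_closed_form(self, geometric_camera):
        table = make_calibration_table(geometric_camera, [200.0], [50.0])
        expected = (
            2 * geometric_camera.pm_x
            * math.sin(math.atan(25.0 / 200.0))
            / math.sin(geometric_camera.phi_x)
        )
        assert table.separation_px[0] == pytest.approx(expected, rel=1e-12)

    def test_separation_halves_when_depth_doubles_paraxially(self, geometric_camera):
        table = make_calibration_table(geometric_camera, [200.0, 400.0], [10.0])
        assert table.separation_px[0] / table.separation_px[1] == pytest.approx(
            2.0, rel=0.01
        )

    def test_empty_spacings_rejected(self, geometric_camera):
        with pytest.raises(ValueError):
            make_calibration_table(geometric_camera, [200.0], [])

    def test_too_wide_spacing_skipped(self, geometric_camera):
        # 400 mm spacing at 150 mm depth projects far outside the frame
        table = make_calibration_table(geometric_camera, [150.0], [400.0, 25.0])
        assert table.spacing_mm == [25.0]


class TestArtificialPlant:
    def test_reference_scale_plant(self, geometric_camera):
        leaves = make_artificial_plant(18, seed=0, model=geometric_camera)
        assert len(leaves) == 18
        assert all(55 <= lf.width_mm <= 115 for lf in leaves)
        assert all(90 <= lf.depth_mm <= 340 for lf in leaves)
        cams = [i * 31.25 for i in range(9)]
        for lf in leaves:
            assert sum(leaf_visible(lf, c, geometric_camera) for c in cams) >= 2

    def test_reproducible_from_seed(self, geometric_camera):
        a = make_artificial_plant(6, seed=5, model=geometric_camera)
        b = make_artificial_plant(6, seed=5, model=geometric_camera)
        assert a == b
        c = make_artificial_plant(6, seed=6, model=geometric_camera)
        assert a != c

    def test_zero_leaves(self, geometric_camera):
        assert make_artificial_plant(0, seed=0, model=geometric_camera) == []


class TestPipelineComposition:
    def test_empty_series_reconstructs_to_nothing(self, selfcal_camera):
        from leafscan.io import ScanSeries

        series = ScanSeries(detections=[], n_images=6, step_mm=30.0)
        assert reconstruct(series, GroupingParams(), selfcal_camera) == []

    def test_single_leaf_scan_yields_single_position(self, selfcal_camera):
        # small leaf on a short traverse: inside the depth model's
        # small-angle validity band, so recovery is tight
        series, _ = render_scan([central_leaf(x=10.0, y=0.0, w=24.0, h=20.0)],
                                6, 4.0, selfcal_camera, NOISE_OFF)
        positions = reconstruct(series, GroupingParams(), selfcal_camera)
        assert len(positions) == 1
        assert positions[0].n_detections == 6
        assert positions[0].depth_mm == pytest.approx(200.0, rel=0.02)
        assert positions[0].x_mm == pytest.approx(10.0, abs=2.0)
        assert positions[0].y_mm == pytest.approx(0.0, abs=2.0)
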