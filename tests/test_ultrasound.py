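import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from atcurve.errors import (
    DegenerateConfigurationError,
    DetectionFailureError,
    InvalidInputError,
    InvalidSyncError,
)
from atcurve.simulate import synth_ultrasound_frame
from atcurve.ultrasound import (
    ProbeCalibration,
    ProbePose,
    UltrasoundFrame,
    detect_skin_line,
    fit_rigid_transform,
    global_to_image,
    image_to_global,
    project_mtj_to_skin,
    synchronize_streams,
)


def _flat_calibration():
    corners = np.array(
        [[0.0, -5.0, 0.0], [60.0, -5.0, 0.0], [60.0, 5.0, 0.0], [0.0, 5.0, 0.0]]
    )
    return ProbeCalibration(corners=corners, depth_sign=1.0)


class TestRigidFit:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3)) * 50
        pose = fit_rigid_transform(pts, pts)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation, 0.0, atol=1e-12)
        assert pose.residual < 1e-12

    def test_recovers_quarter_turn_and_shift(self, rng):
        src = rng.normal(size=(4, 3)) * 30
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([10.0, 0.0, 0.0])
        pose = fit_rigid_transform(src, src @ R.T + t)
        np.testing.assert_allclose(pose.rotation, R, atol=1e-9)
        np.testing.assert_allclose(pose.translation, t, atol=1e-9)
        assert pose.residual < 1e-9

    def test_noisy_fit_matches_scipy_oracle(self, rng):
        src = rng.normal(size=(6, 3)) * 40
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(size=3) * 20
        tgt = src @ R.T + t + rng.normal(0, 0.2, src.shape)
        pose = fit_rigid_transform(src, tgt)
        # independent oracle: scipy's Kabsch on centred clouds
        rot, rssd = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
        np.testing.assert_allclose(pose.rotation, rot.as_matrix(), atol=1e-8)
        assert pose.residual == pytest.approx(rssd / np.sqrt(len(src)), rel=1e-6)

    def test_residual_matches_coarse_rotation_grid_search(self, rng):
        # brute-force oracle: no better rotation exists on a coarse SO(3) grid
        src = rng.normal(size=(4, 3)) * 25
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        tgt = src @ R.T + np.array([5.0, -2.0, 7.0]) + rng.normal(0, 0.2, src.shape)
        pose = fit_rigid_transform(src, tgt)
        best = np.inf
        grid = np.arange(-180, 180, 30)
        sc, gc = src.mean(0), tgt.mean(0)
        for a in grid:
            for b in np.arange(-90, 91, 30):
                for c in grid:
                    Rg = Rotation.from_euler("xyz", [a, b, c], degrees=True).as_matrix()
                    res = np.sqrt(
                        np.mean(np.sum(((src - sc) @ Rg.T - (tgt - gc)) ** 2, axis=1))
                    )
                    best = min(best, res)
        assert pose.residual <= best + 1e-9

    def test_collinear_source_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateConfigurationError):
            fit_rigid_transform(src, src)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_rigid_transform(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_idempotence(self, rng):
        src = rng.normal(size=(5, 3)) * 30
        R = Rotation.random(random_state=9).as_matrix()
        pose = fit_rigid_transform(src, src @ R.T + [1.0, 2.0, 3.0])
        again = fit_rigid_transform(pose.apply(src), src @ R.T + [1.0, 2.0, 3.0])
        np.testing.assert_allclose(again.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(again.translation, 0.0, atol=1e-9)

    def test_reflection_never_returned(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            src = r.normal(size=(4, 3)) * 10
            tgt = r.normal(size=(4, 3)) * 10
            pose = fit_rigid_transform(src, tgt)
            assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)


class TestSkinDetection:
    def test_flat_bright_row_detected_exactly(self):
        img = np.zeros((64, 120))
        img[20, :] = 1.0
        line = detect_skin_line(UltrasoundFrame(img))
        assert line.shape[0] >= 60
        np.testing.assert_array_equal(line[:, 0], 20.0)

    def test_planted_ramp_within_one_pixel(self):
        frame = synth_ultrasound_frame(
            np.linspace(10, 30, 200), mtj_px=None, noise=0.04, shape=(80, 200),
            rng=np.random.default_rng(5),
        )
        line = detect_skin_line(frame)
        # the renderer draws the band from the first integer row at/below the
        # continuous profile, so that row is the planted ground truth
        planted = np.ceil(np.linspace(10, 30, 200))[line[:, 1].astype(int)]
        assert np.abs(line[:, 0] - planted).max() <= 1.0

    def test_all_zero_image_fails(self):
        with pytest.raises(DetectionFailureError):
            detect_skin_line(UltrasoundFrame(np.zeros((32, 32))))


class TestProjection:
    def test_perpendicular_foot(self):
        skin = np.column_stack([np.full(100, 5.0), np.arange(100.0)])
        np.testing.assert_allclose(project_mtj_to_skin((20.0, 40.0), skin), [5.0, 40.0])

    def test_point_on_line_returns_itself(self):
        skin = np.array([[0.0, 0.0], [10.0, 10.0]])
        np.testing.assert_allclose(project_mtj_to_skin((5.0, 5.0), skin), [5.0, 5.0])

    def test_empty_polyline_rejected(self):
        with pytest.raises(InvalidInputError):
            project_mtj_to_skin((0.0, 0.0), np.empty((0, 2)))

    def test_matches_brute_force_segment_oracle(self, rng):
        for _ in range(30):
            line = rng.normal(size=(8, 2)) * 20
            p = rng.normal(size=2) * 20
            got = project_mtj_to_skin(p, line)
            best, bd = None, np.inf
            for a, b in zip(line[:-1], line[1:]):
                for t in np.linspace(0, 1, 2001):
                    c = a + t * (b - a)
                    d = np.hypot(*(c - p))
                    if d < bd:
                        best, bd = c, d
            assert np.hypot(*(got - p)) <= bd + 1e-6

    def test_never_farther_than_any_vertex(self, rng):
        line = rng.normal(size=(6, 2)) * 15
        p = rng.normal(size=2) * 15
        got = project_mtj_to_skin(p, line)
        d = np.hypot(*(got - p))
        assert d <= np.min(np.hypot(line[:, 0] - p[0], line[:, 1] - p[1])) + 1e-12


class TestImageToGlobal:
    def test_documented_axis_mapping(self):
        calib = _flat_calibration()
        pose = ProbePose(np.eye(3), np.zeros(3))
        frame = UltrasoundFrame(np.zeros((4, 4)), spacing=(0.1, 0.1))
        # anchor = left-center (0,0,0); columns along +x, rows along +z
        got = image_to_global((10.0, 20.0), frame, calib, pose)
        np.testing.assert_allclose(got, [2.0, 0.0, 1.0], atol=1e-12)

    def test_round_trip_under_random_pose(self, rng):
        calib = _flat_calibration()
        frame = UltrasoundFrame(np.zeros((4, 4)), spacing=(0.08, 0.12))
        R = Rotation.random(random_state=17).as_matrix()
        pose = ProbePose(R, rng.normal(size=3) * 100)
        for _ in range(10):
            px = rng.uniform(0, 500, size=2)
            world = image_to_global(px, frame, calib, pose)
            back = global_to_image(world, frame, calib, pose)
            np.testing.assert_allclose(back, px, atol=1e-9)

    def test_full_chain_recovers_planted_mtj(self, walking_trial):
        """Render a frame, detect skin, project the MTJ, map to global: the
        result must land on the planted skin point within pixel+noise scale."""
        us = walking_trial.ultrasound
        i = 200
        frame = us.frame(i)
        skin = detect_skin_line(frame)
        proj = project_mtj_to_skin(us.mtj_px[i], skin)
        world = image_to_global(proj, frame, us.calibration, us.poses[i])
        err = np.linalg.norm(world - us.skin_point_world_true[i])
        tol = us.pixel_spacing * (1 + us.mtj_px[i].shape[0]) + 3 * walking_trial.params.pixel_noise * us.pixel_spacing + 0.3
        assert err < tol

    def test_projected_depth_matches_planted_depth(self, walking_trial):
        us = walking_trial.ultrasound
        i = 57
        frame = us.frame(i)
        skin = detect_skin_line(frame)
        proj = project_mtj_to_skin(us.mtj_px_true[i], skin)
        depth_px = np.linalg.norm(proj - us.mtj_px_true[i])
        assert depth_px * us.pixel_spacing == pytest.approx(us.mtj_depth_mm, abs=us.pixel_spacing * 1.5)


class TestSync:
    def test_equal_rates_identity(self):
        m = synchronize_streams(100, 100, 0, 0, 10)
        np.testing.assert_array_equal(m, np.arange(10))

    def test_146_to_250_arithmetic(self):
        m = synchronize_streams(146, 250, 0, 0, 250)
        np.testing.assert_array_equal(m, np.round(np.arange(250) * 146 / 250))

    def test_round_trip_within_half_sample(self, rng):
        for _ in range(10):
            us_rate = rng.uniform(50, 300)
            mocap_rate = rng.uniform(50, 300)
            m = synchronize_streams(us_rate, mocap_rate, 5, 7, 200, mode="linear")
            # mapping back to mocap time must land within half a us sample
            t_mocap = (np.arange(200) - 7) / mocap_rate
            t_us = (m - 5) / us_rate
            assert np.abs(t_us - t_mocap).max() <= 0.5 / us_rate + 1e-12

    def test_trigger_outside_recording(self):
        with pytest.raises(InvalidSyncError):
            synchronize_streams(146, 250, 0, 500, 250)
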