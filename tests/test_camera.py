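import numpy as np
import pytest

from oracles import project_point_scalar

from endonav.camera import (
    CameraIntrinsics,
    DepthMap,
    backproject_depth,
    calibrate_intrinsics_zhang,
    distort_normalized,
    estimate_planar_pose,
    homography_dlt,
    load_depth_map,
    load_intrinsics_json,
    project,
    save_depth_map,
    save_intrinsics_json,
    undistort_normalized,
)
from endonav.errors import CalibrationError, DegenerateGeometryError
from endonav.fiducial_board import BoardDetection, make_board
from endonav.geometry3d import RigidTransform, pose_error, random_pose


class TestIntrinsics:
    def test_validation(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=-1, fy=1, cx=0, cy=0)
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=100, fy=100, cx=5000, cy=240, width=640, height=480)

    def test_json_roundtrip(self, tmp_path, intrinsics_distorted):
        p = tmp_path / "intr.json"
        save_intrinsics_json(intrinsics_distorted, p)
        loaded = load_intrinsics_json(p)
        for name in ("fx", "fy", "cx", "cy", "skew", "width", "height"):
            assert getattr(loaded, name) == getattr(intrinsics_distorted, name)
        np.testing.assert_array_equal(loaded.dist, intrinsics_distorted.dist)


class TestProject:
    def test_optical_axis_maps_to_principal_point(self, intrinsics):
        for depth in (1.0, 57.0, 4000.0):
            uv, vis = project(
                intrinsics, RigidTransform.identity(), np.array([[0.0, 0, depth]])
            )
            np.testing.assert_allclose(uv[0], [intrinsics.cx, intrinsics.cy], atol=1e-12)
            assert vis[0]

    def test_similar_triangles(self, intrinsics):
        d = 123.0
        uv, _ = project(intrinsics, RigidTransform.identity(), np.array([[d, 0, d]]))
        np.testing.assert_allclose(
            uv[0], [intrinsics.cx + intrinsics.fx, intrinsics.cy], atol=1e-9
        )

    def test_matches_scalar_oracle_with_distortion(self, intrinsics_distorted, rng):
        cam = random_pose(2, 20, 30)
        pts = rng.uniform(-30, 30, size=(50, 3))
        pts[:, 2] = rng.uniform(150, 400, size=50)
        pts = cam.invert().apply(pts)  # ensure in front after transform
        uv, _ = project(intrinsics_distorted, cam, pts)
        for p, u in zip(pts, uv):
            expected = project_point_scalar(
                intrinsics_distorted, cam.rotation, cam.translation, p
            )
            np.testing.assert_allclose(u, expected, atol=1e-10)

    def test_behind_camera_flagged_not_raised(self, intrinsics):
        uv, vis = project(
            intrinsics, RigidTransform.identity(), np.array([[0.0, 0, -10]])
        )
        assert not vis[0]

    def test_outside_image_flagged(self, intrinsics):
        uv, vis = project(
            intrinsics, RigidTransform.identity(), np.array([[1000.0, 0, 10.0]])
        )
        assert not vis[0]


class TestDistortion:
    def test_undistort_inverts_distort(self, rng):
        dist = np.array([-0.2, 0.05, 0.001, -0.002, 0.01])
        xy = rng.uniform(-0.3, 0.3, size=(200, 2))
        back = undistort_normalized(distort_normalized(xy, dist), dist)
        np.testing.assert_allclose(back, xy, atol=1e-8)


class TestBackprojectDepth:
    def test_single_pixel_on_axis(self, intrinsics):
        depth = np.zeros((480, 640))
        depth[int(intrinsics.cy), int(intrinsics.cx)] = 77.0
        cloud = backproject_depth(DepthMap(depth, intrinsics))
        assert len(cloud) == 1
        np.testing.assert_allclose(cloud.points[0], [0, 0, 77.0], atol=1e-9)

    def test_plane_roundtrip(self, intrinsics):
        # analytic depth map of the plane z = 100 (zero distortion)
        depth = np.full((480, 640), 100.0)
        cloud = backproject_depth(DepthMap(depth, intrinsics))
        assert len(cloud) == 480 * 640
        np.testing.assert_allclose(cloud.points[:, 2], 100.0, atol=1e-6)

    def test_project_backproject_roundtrip(self, intrinsics_distorted, rng):
        pts = np.column_stack([
            rng.uniform(-40, 40, 200), rng.uniform(-30, 30, 200),
            rng.uniform(120, 300, 200),
        ])
        uv, vis = project(intrinsics_distorted, RigidTransform.identity(), pts)
        assert vis.all()
        from endonav.camera import _pixels_to_normalized

        xy = _pixels_to_normalized(intrinsics_distorted, uv)
        rec = np.column_stack([xy * pts[:, 2:3], pts[:, 2]])
        np.testing.assert_allclose(rec, pts, atol=1e-6)

    def test_empty_map_allowed_and_flagged(self, intrinsics):
        dm = DepthMap(np.zeros((10, 12)), intrinsics)
        assert dm.is_empty
        assert len(backproject_depth(dm)) == 0

    def test_negative_depth_rejected(self, intrinsics):
        bad = np.zeros((4, 4))
        bad[1, 1] = -3.0
        with pytest.raises(ValueError):
            DepthMap(bad, intrinsics)

    def test_png_sidecar_roundtrip_bit_exact(self, tmp_path, intrinsics, rng):
        depth = np.where(rng.random((60, 80)) > 0.3, rng.uniform(50, 500, (60, 80)), 0.0)
        dm = DepthMap(depth, intrinsics)
        scale = 0.05
        save_depth_map(dm, tmp_path / "d.png", scale_mm=scale)
        loaded = load_depth_map(tmp_path / "d.png")
        np.testing.assert_array_equal(
            np.round(loaded.depth / scale), np.round(dm.depth / scale)
        )
        assert loaded.intrinsics.fx == intrinsics.fx


def synth_views(board, intr, n_views, seed=0, noise_px=0.0):
    """Noise-controlled synthetic calibration views with known poses."""
    rng = np.random.default_rng(seed)
    dets, poses = [], []
    center = np.append(board.points_mm.mean(axis=0), 0.0)
    for i in range(n_views):
        rv = rng.uniform(-25, 25, size=3) * [1, 1, 2]
        pose = RigidTransform.from_rotvec_deg(
            rv, -RigidTransform.from_rotvec_deg(rv).apply(center)
            + [rng.uniform(-20, 20), rng.uniform(-20, 20), rng.uniform(380, 550)],
        )
        uv, _ = project(intr, pose, board.points_3d)
        if noise_px:
            uv = uv + rng.normal(scale=noise_px, size=uv.shape)
        dets.append(BoardDetection(i, "cam", board.point_ids, uv))
        poses.append(pose)
    return dets, poses


class TestZhangCalibration:
    board = make_board(5, 9, 20.0)

    def test_recovers_intrinsics_noiseless(self, intrinsics):
        dets, _ = synth_views(self.board, intrinsics, 10, seed=3)
        est, rms = calibrate_intrinsics_zhang(
            self.board, dets, refine=True, image_size=(640, 480)
        )
        for name in ("fx", "fy", "cx", "cy"):
            assert getattr(est, name) == pytest.approx(
                getattr(intrinsics, name), rel=1e-6
            )
        assert max(rms) < 1e-6

    def test_two_views_rejected(self, intrinsics):
        dets, _ = synth_views(self.board, intrinsics, 2)
        with pytest.raises(CalibrationError):
            calibrate_intrinsics_zhang(self.board, dets, image_size=(640, 480))

    def test_recovers_k1(self):
        truth = CameraIntrinsics(
            fx=800.0, fy=820.0, cx=320.0, cy=240.0,
            dist=np.array([-0.2, 0, 0, 0, 0]), width=640, height=480,
        )
        dets, _ = synth_views(self.board, truth, 12, seed=5)
        est, rms = calibrate_intrinsics_zhang(
            self.board, dets, refine=True, image_size=(640, 480)
        )
        assert est.dist[0] == pytest.approx(-0.2, abs=1e-4)
        assert max(rms) < 1e-6

    def test_view_relabeling_invariance(self, intrinsics):
        dets, _ = synth_views(self.board, intrinsics, 8, seed=9, noise_px=0.3)
        # closed form is a deterministic function of the (unordered) view set
        cf1, _ = calibrate_intrinsics_zhang(
            self.board, dets, refine=False, image_size=(640, 480)
        )
        cf2, _ = calibrate_intrinsics_zhang(
            self.board, dets[::-1], refine=False, image_size=(640, 480)
        )
        assert cf1.fx == pytest.approx(cf2.fx, rel=1e-9)
        assert cf1.cx == pytest.approx(cf2.cx, rel=1e-9)
        # refined estimates agree to optimizer precision
        est1, _ = calibrate_intrinsics_zhang(self.board, dets, image_size=(640, 480))
        est2, _ = calibrate_intrinsics_zhang(
            self.board, dets[::-1], image_size=(640, 480)
        )
        assert est1.fx == pytest.approx(est2.fx, rel=1e-5)
        assert est1.cx == pytest.approx(est2.cx, rel=1e-5)

    def test_degenerate_pure_translation_views(self, intrinsics):
        rng = np.random.default_rng(0)
        dets = []
        for i in range(6):  # identical rotation, translation-only motion
            pose = RigidTransform(np.eye(3), [rng.uniform(-20, 20),
                                              rng.uniform(-20, 20), 450 + 20 * i])
            uv, _ = project(intrinsics, pose, self.board.points_3d)
            dets.append(BoardDetection(i, "cam", self.board.point_ids, uv))
        with pytest.raises(CalibrationError):
            calibrate_intrinsics_zhang(self.board, dets, image_size=(640, 480))


class TestPlanarPose:
    board = make_board(5, 9, 20.0)

    def make_pose(self, seed=0):
        center = np.append(self.board.points_mm.mean(axis=0), 0.0)
        r = RigidTransform.from_rotvec_deg((15.0, -20.0, 8.0))
        return RigidTransform(r.rotation, -r.apply(center) + [5.0, -8.0, 300.0])

    def test_noiseless_recovery(self, intrinsics):
        pose = self.make_pose()
        uv, _ = project(intrinsics, pose, self.board.points_3d)
        est, rms = estimate_planar_pose(intrinsics, self.board.points_mm, uv)
        ang, trans = pose_error(est, pose)
        assert ang < 1e-6 and trans < 1e-6
        assert rms < 1e-8

    def test_noiseless_recovery_with_distortion(self, intrinsics_distorted):
        pose = self.make_pose()
        uv, _ = project(intrinsics_distorted, pose, self.board.points_3d)
        est, rms = estimate_planar_pose(intrinsics_distorted, self.board.points_mm, uv)
        ang, trans = pose_error(est, pose)
        assert ang < 1e-5 and trans < 1e-4

    def test_three_points_rejected(self, intrinsics):
        with pytest.raises(DegenerateGeometryError):
            estimate_planar_pose(
                intrinsics, self.board.points_mm[:3], np.zeros((3, 2))
            )

    def test_collinear_rejected(self, intrinsics):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            estimate_planar_pose(intrinsics, pts, np.column_stack([np.arange(5.0), np.ones(5)]))

    def test_noisy_pose_within_stated_bounds(self, intrinsics, rng):
        pose = self.make_pose()
        uv, _ = project(intrinsics, pose, self.board.points_3d)
        for seed in range(10):
            noisy = uv + np.random.default_rng(seed).normal(scale=0.5, size=uv.shape)
            est, rms = estimate_planar_pose(intrinsics, self.board.points_mm, noisy)
            ang, trans = pose_error(est, pose)
            assert ang < 1.0 and trans < 5.0  # at ~300 mm range
            assert rms <= 1.0

    def test_refinement_never_increases_rms(self, intrinsics, rng):
        pose = self.make_pose()
        uv, _ = project(intrinsics, pose, self.board.points_3d)
        uv = uv + rng.normal(scale=0.7, size=uv.shape)
        _, rms_raw = estimate_planar_pose(intrinsics, self.board.points_mm, uv, refine=False)
        _, rms_ref = estimate_planar_pose(intrinsics, self.board.points_mm, uv, refine=True)
        assert rms_ref <= rms_raw + 1e-12


class TestHomography:
    def test_exact_on_synthetic(self, rng):
        h_true = np.array([[1.2, 0.1, 5.0], [-0.05, 0.9, -3.0], [1e-4, -2e-4, 1.0]])
        src = rng.uniform(-50, 50, size=(20, 2))
        hom = np.column_stack([src, np.ones(20)]) @ h_true.T
        dst = hom[:, :2] / hom[:, 2:3]
        h = homography_dlt(src, dst)
        np.testing.assert_allclose(h, h_true, atol=1e-9)
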