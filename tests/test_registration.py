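import numpy as np
import pytest

from oracles import brute_force_rigid_fit, plain_point_to_plane_icp, rotation_angle_deg

from endonav.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    NoOverlapError,
)
from endonav.geometry3d import RigidTransform, pose_error, random_pose
from endonav.registration import (
    ICPConfig,
    MeshProximity,
    PointCloud,
    compose_ct_to_reference,
    estimate_normals,
    icp_point_to_plane_robust,
    initial_align_from_prior,
    procrustes_register,
    sample_surface,
    tukey_weight,
)


class TestEstimateNormals:
    def test_plane(self, rng):
        pts = np.column_stack([rng.uniform(-50, 50, (200, 2)), np.zeros(200)])
        cloud = estimate_normals(PointCloud(pts), k_neighbors=10, viewpoint=(0, 0, 100))
        np.testing.assert_allclose(cloud.normals, [[0, 0, 1]] * 200, atol=1e-6)

    def test_sphere_normals_antiparallel_to_radius(self):
        # dense, even coverage (Fibonacci lattice) so each k-NN patch is flat
        n = 20_000
        i = np.arange(n)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(1.0 - z * z)
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        pts = 50.0 * dirs
        cloud = estimate_normals(PointCloud(pts), k_neighbors=10, viewpoint=(0, 0, 0))
        cosang = np.einsum("ni,ni->n", cloud.normals, -dirs)
        angles = np.rad2deg(np.arccos(np.clip(cosang, -1, 1)))
        assert angles.max() < 2.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            estimate_normals(PointCloud(np.zeros((2, 3))), k_neighbors=3)


class TestInitialAlign:
    def test_identity_prior_is_noop(self, face_mesh):
        moved = initial_align_from_prior(face_mesh, RigidTransform.identity())
        np.testing.assert_array_equal(moved.vertices, face_mesh.vertices)

    def test_truth_prior_converges_immediately(self, face_mesh):
        source = sample_surface(face_mesh, 800, seed=0)
        res = icp_point_to_plane_robust(source, face_mesh, ICPConfig())
        assert res.iterations <= 2
        assert res.converged
        ang, trans = pose_error(res.transform, RigidTransform.identity())
        assert ang < 1e-9 and trans < 1e-9

    def test_basin_recovery_from_15deg_20mm(self, face_mesh):
        offset = random_pose(3, 15.0, 20.0)
        source = sample_surface(face_mesh, 1000, seed=1)
        displaced = PointCloud(offset.apply(source.points))
        res = icp_point_to_plane_robust(displaced, face_mesh, ICPConfig())
        ang, trans = pose_error(res.transform, offset.invert())
        assert ang < 0.05 and trans < 0.05


class TestRobustICP:
    def test_self_registration_is_identity(self, face_mesh):
        target = sample_surface(face_mesh, 600, seed=2, with_normals=True)
        res = icp_point_to_plane_robust(PointCloud(target.points), target, ICPConfig())
        assert res.iterations == 1
        assert res.converged
        assert res.final_cost == pytest.approx(0.0, abs=1e-20)
        ang, trans = pose_error(res.transform, RigidTransform.identity())
        assert ang < 1e-10 and trans < 1e-10

    def test_known_displacement_recovery(self, face_mesh):
        truth = RigidTransform.from_rotvec_deg((3.0, -2.0, 3.0), (3.0, -2.0, 2.5))
        source = PointCloud(truth.invert().apply(sample_surface(face_mesh, 1200, 3).points))
        res = icp_point_to_plane_robust(source, face_mesh, ICPConfig())
        ang, trans = pose_error(res.transform, truth)
        assert ang < 1e-4 and trans < 1e-3

    def test_outliers_vs_clean_subset_oracle(self, face_mesh, rng):
        # 20% gross outliers; oracle = unweighted ICP on the clean subset
        truth = RigidTransform.from_rotvec_deg((2.0, 3.0, -1.0), (4.0, -3.0, 2.0))
        surf = sample_surface(face_mesh, 1200, 4, with_normals=True)
        clean = truth.invert().apply(surf.points)
        n_out = len(clean) // 5
        pick = rng.choice(len(clean), n_out, replace=False)
        # displace along the outward normal: guaranteed >= 5 mm off-surface
        outliers = truth.invert().apply(
            surf.points[pick] + surf.normals[pick] * rng.uniform(5.0, 25.0, (n_out, 1))
        )
        source = PointCloud(np.vstack([clean, outliers]))

        res = icp_point_to_plane_robust(source, face_mesh, ICPConfig())
        ang, trans = pose_error(res.transform, truth)
        assert ang < 0.1 and trans < 0.1

        target = sample_surface(face_mesh, 8000, seed=5, with_normals=True)
        r_o, t_o = plain_point_to_plane_icp(clean, target.points, target.normals)
        assert rotation_angle_deg(res.transform.rotation, r_o) < 0.05
        assert np.linalg.norm(res.transform.translation - t_o) < 0.05

        # outliers must carry zero weight at convergence: all sit beyond the
        # 1 mm gate, so they are rejected before weighting even applies
        prox = MeshProximity(face_mesh)
        moved = res.transform.apply(outliers)
        _, _, d = prox.query(moved)
        assert (d > 1.0).all()
        assert (tukey_weight(d, max(0.1, 6 * np.median(d))) >= 0).all()  # defined

    def test_no_overlap_failure_carries_transform(self):
        rng = np.random.default_rng(0)
        src = PointCloud(rng.normal(size=(50, 3)))
        tgt = estimate_normals(
            PointCloud(rng.normal(size=(100, 3)) + [0, 0, 500.0]), 5, viewpoint=(0, 0, 600)
        )
        cfg = ICPConfig(max_correspondence_mm=1.0, adaptive=False)
        with pytest.raises(NoOverlapError) as exc:
            icp_point_to_plane_robust(src, tgt, cfg)
        assert exc.value.last_transform is not None

    def test_source_too_small(self, face_mesh):
        with pytest.raises(InsufficientDataError):
            icp_point_to_plane_robust(PointCloud(np.zeros((5, 3))), face_mesh)

    def test_final_cost_not_above_initial(self, face_mesh):
        offset = random_pose(9, 10.0, 10.0)
        source = PointCloud(offset.apply(sample_surface(face_mesh, 700, 6).points))
        res = icp_point_to_plane_robust(source, face_mesh, ICPConfig(max_iterations=30))
        # re-evaluate the robust cost of the *initial* alignment with the
        # final kernel scale: converged cost must not exceed it
        prox = MeshProximity(face_mesh)
        _, n, d = prox.query(source.points)
        assert res.final_cost <= np.mean(d**2) + 1e-12

    def test_limit_equivalence_with_least_squares(self, face_mesh):
        offset = random_pose(11, 5.0, 5.0)
        source = PointCloud(offset.apply(sample_surface(face_mesh, 900, 7).points))
        big = 1e9
        precise = dict(adaptive=False, plateau_tol=0.0, rel_tol=1e-14, max_iterations=120)
        cfg_t = ICPConfig(kernel="tukey", k_mm=big, max_correspondence_mm=big, **precise)
        cfg_l = ICPConfig(kernel="none", k_mm=1.0, max_correspondence_mm=big, **precise)
        res_t = icp_point_to_plane_robust(source, face_mesh, cfg_t)
        res_l = icp_point_to_plane_robust(source, face_mesh, cfg_l)
        ang, trans = pose_error(res_t.transform, res_l.transform)
        assert ang < 1e-6 and trans < 1e-6


class TestTukeyKernel:
    def test_anchor_values(self):
        assert tukey_weight(np.array([0.0]), 0.1)[0] == 1.0
        assert tukey_weight(np.array([0.1]), 0.1)[0] == pytest.approx(0.0, abs=1e-30)
        assert tukey_weight(np.array([-0.1]), 0.1)[0] == pytest.approx(0.0, abs=1e-30)
        assert tukey_weight(np.array([5.0]), 0.1)[0] == 0.0

    def test_monotone_nonincreasing_on_grid(self):
        k = 0.1
        r = np.linspace(0.0, k, 10_000)
        w = tukey_weight(r, k)
        assert np.all(np.diff(w) <= 1e-15)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)


class TestProcrustes:
    def fiducials(self):
        ang = 2 * np.pi * np.arange(7) / 7
        return np.column_stack([80 * np.cos(ang), 60 * np.sin(ang), np.zeros(7)])

    def test_exact_recovery(self):
        src = self.fiducials()
        truth = random_pose(1, 40.0, 90.0)
        t, fre = procrustes_register(src, truth.apply(src))
        ang, trans = pose_error(t, truth)
        assert ang < 1e-9 and trans < 1e-9
        assert fre == pytest.approx(0.0, abs=1e-9)

    def test_fre_matches_brute_force_optimizer(self):
        src = self.fiducials()
        truth = random_pose(2, 30.0, 50.0)
        for seed in range(10):
            noisy = truth.apply(src) + np.random.default_rng(seed).normal(
                scale=0.3, size=src.shape
            )
            t, fre = procrustes_register(src, noisy)
            _, _, rms_oracle = brute_force_rigid_fit(src, noisy)
            assert fre == pytest.approx(rms_oracle, abs=1e-6)

    def test_collinear_rejected(self):
        src = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            procrustes_register(src, src + 1.0)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            procrustes_register(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_invariant_under_common_rigid_motion(self):
        src = self.fiducials()
        noisy = random_pose(3, 20, 30).apply(src) + np.random.default_rng(7).normal(
            scale=0.5, size=src.shape
        )
        _, fre0 = procrustes_register(src, noisy)
        g = random_pose(4, 60, 120)
        _, fre1 = procrustes_register(g.apply(src), g.apply(noisy))
        assert fre1 == pytest.approx(fre0, abs=1e-9)

    def test_reflection_guard(self):
        # near-planar configuration displaced so naive SVD could reflect
        src = self.fiducials()
        truth = RigidTransform.from_rotvec_deg((0, 179.0, 0), (5.0, 5.0, 5.0))
        t, fre = procrustes_register(src, truth.apply(src))
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert fre < 1e-9


class TestComposeCtToReference:
    def test_identities(self):
        out = compose_ct_to_reference(RigidTransform.identity(), RigidTransform.identity())
        np.testing.assert_allclose(out.matrix(), np.eye(4), atol=1e-15)

    def test_matches_simulation_truth(self, phantom):
        cam_from_board = random_pose(5, 30.0, 200.0)
        cam_from_ct = cam_from_board.compose(phantom.board_from_ct)
        est = compose_ct_to_reference(cam_from_ct, cam_from_board)
        ang, trans = pose_error(est, phantom.board_from_ct)
        assert ang < 1e-9 and trans < 1e-9

    def test_chain_closure_at_registration_frame(self, phantom):
        from endonav.overlay_eval import our_chain_transform

        cam_from_board = random_pose(6, 30.0, 200.0)
        cam_from_ct = cam_from_board.compose(phantom.board_from_ct)
        board_from_ct = compose_ct_to_reference(cam_from_ct, cam_from_board)
        chain = our_chain_transform(
            cam_from_board, RigidTransform.identity(), board_from_ct
        )
        np.testing.assert_allclose(chain.matrix(), cam_from_ct.matrix(), atol=1e-9)


class TestMeshProximity:
    def test_exact_against_brute_force(self, face_mesh, rng):
        from endonav.registration import _closest_point_on_triangles

        pts = sample_surface(face_mesh, 150, 9).points + rng.normal(scale=2.0, size=(150, 3))
        prox = MeshProximity(face_mesh)
        _, _, d = prox.query(pts)
        v, f = face_mesh.vertices, face_mesh.faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        for p, dist in zip(pts, d):
            brute = np.linalg.norm(
                _closest_point_on_triangles(p[None, :], a, b, c) - p, axis=1
            ).min()
            assert dist == pytest.approx(brute, abs=1e-9)
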