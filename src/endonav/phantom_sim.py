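"""Synthetic phantom and sensor simulator.

Generates every input the navigation pipeline consumes: a parametric
face-like surface (half-ellipsoid with a nose ridge), an interior 10 mm grid
of spherical targets, seven base fiducials, a board mount, and seeded noisy
observations from the depth camera, the marker boards, and the IR tracker.

Every observation is a pure function of (inputs, seed). A master seed fans
out to per-stage child seeds via :func:`derive_rng`, which hashes string
labels into a ``numpy.random.SeedSequence``, so any stage can be re-run in
isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .camera import CameraIntrinsics, DepthMap
from .errors import InsufficientDataError
from .fiducial_board import BoardDetection, MarkerBoard
from .geometry3d import RigidTransform, transform_from_dict, transform_to_dict
from .ir_baseline import FiducialSet, TrackerFrame
from .registration import SurfaceMesh

__all__ = [
    "PhantomParams",
    "PhantomModel",
    "NoiseConfig",
    "make_phantom",
    "simulated_ct_surface",
    "render_depth",
    "observe_board",
    "observe_tracker",
    "derive_rng",
    "mesh_audit",
    "write_fixture_set",
]


def derive_rng(master_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic child generator for a stage, keyed by string labels.

    Entropy is ``[master_seed, crc32(label_0), crc32(label_1), ...]`` fed to a
    ``SeedSequence``; the same (seed, labels) always gives the same stream.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF]
    entropy += [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomParams:
    """Parametric description of the synthetic head phantom (mm)."""

    half_axes: tuple[float, float, float] = (90.0, 70.0, 110.0)
    nose_height_mm: float = 12.0
    nose_sigma_rad: float = 0.25
    nose_direction: tuple[float, float, float] = (0.0, -0.35, 0.94)
    n_rings: int = 24
    n_segments: int = 48
    grid_rows: int = 5
    grid_cols: int = 5
    grid_pitch_mm: float = 10.0
    grid_depth_mm: float = 40.0
    n_fiducials: int = 7

    def __post_init__(self):
        if min(self.half_axes) <= 0:
            raise ValueError("half axes must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.n_rings < 3 or self.n_segments < 6:
            raise ValueError("mesh resolution too low")


@dataclass(frozen=True)
class PhantomModel:
    """Ground truth for one simulated phantom instance. CT frame is +z = face."""

    face_mesh: SurfaceMesh
    targets_ct: np.ndarray  # (M, 3) grid-target centres, CT frame
    fiducials: FiducialSet  # on the base perimeter, CT frame
    board_from_ct: RigidTransform  # board mount on the holder
    world_from_ct: RigidTransform  # holder pose
    patientref_from_ct: RigidTransform  # IR patient-reference body on the holder
    params: PhantomParams


def _ellipsoid_face_mesh(params: PhantomParams) -> SurfaceMesh:
    a, b, c = params.half_axes
    n_rings, n_seg = params.n_rings, params.n_segments

    verts = [np.array([0.0, 0.0, c])]
    for i in range(1, n_rings + 1):
        theta = (i / n_rings) * (np.pi / 2.0)
        phi = 2.0 * np.pi * np.arange(n_seg) / n_seg
        ring = np.column_stack([
            a * np.sin(theta) * np.cos(phi),
            b * np.sin(theta) * np.sin(phi),
            np.full(n_seg, c * np.cos(theta)),
        ])
        verts.append(ring)
    verts = np.vstack([verts[0][None, :], *verts[1:]])

    faces = []
    # apex fan
    for j in range(n_seg):
        faces.append([0, 1 + j, 1 + (j + 1) % n_seg])
    # quad strips
    for i in range(n_rings - 1):
        r0, r1 = 1 + i * n_seg, 1 + (i + 1) * n_seg
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    faces = np.asarray(faces, dtype=np.int64)

    # nose ridge: radial bump weighted by angular distance to the nose axis
    d0 = np.asarray(params.nose_direction, dtype=float)
    d0 /= np.linalg.norm(d0)
    unit = verts / np.asarray([a, b, c])
    norms = np.linalg.norm(unit, axis=1, keepdims=True)
    unit = unit / np.maximum(norms, 1e-12)
    ang = np.arccos(np.clip(unit @ d0, -1.0, 1.0))
    bump = params.nose_height_mm * np.exp(-(ang**2) / (2.0 * params.nose_sigma_rad**2))
    radial = verts / np.maximum(np.linalg.norm(verts, axis=1, keepdims=True), 1e-12)
    verts = verts + radial * bump[:, None]

    # enforce outward winding (surface is star-shaped about the origin)
    mesh = SurfaceMesh(verts, faces)
    centroids = verts[faces].mean(axis=1)
    flip = np.einsum("fi,fi->f", mesh.face_normals(), centroids) < 0
    fixed = faces.copy()
    fixed[flip] = fixed[flip][:, ::-1]
    return SurfaceMesh(verts, fixed)


def make_phantom(params: PhantomParams = PhantomParams(), seed: int = 0) -> PhantomModel:
    """Build a deterministic phantom instance (the seed is reserved for
    randomized variants; the default geometry is fully parametric)."""
    mesh = _ellipsoid_face_mesh(params)

    gr, gc, pitch = params.grid_rows, params.grid_cols, params.grid_pitch_mm
    xs = (np.arange(gc) - (gc - 1) / 2.0) * pitch
    ys = (np.arange(gr) - (gr - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack(
        [gx.ravel(), gy.ravel(), np.full(gr * gc, params.grid_depth_mm)]
    )

    a, b, _ = params.half_axes
    alphas = 2.0 * np.pi * np.arange(params.n_fiducials) / params.n_fiducials
    fid_pts = np.column_stack(
        [0.95 * a * np.cos(alphas), 0.95 * b * np.sin(alphas), np.zeros_like(alphas)]
    )
    fiducials = FiducialSet(
        ids=np.arange(params.n_fiducials), points_ct=fid_pts
    )

    ct_from_board = RigidTransform(
        Rotation.from_euler("x", 6.0, degrees=True).as_matrix(),
        np.array([130.0, -60.0, 0.0]),
    )
    world_from_ct = RigidTransform(
        Rotation.from_rotvec(np.deg2rad([2.0, -1.5, 3.0])).as_matrix(),
        np.array([4.0, -7.0, 2.5]),
    )
    ct_from_patientref = RigidTransform(
        Rotation.from_euler("z", 15.0, degrees=True).as_matrix(),
        np.array([-140.0, -80.0, 0.0]),
    )

    return PhantomModel(
        face_mesh=mesh,
        targets_ct=targets,
        fiducials=fiducials,
        board_from_ct=ct_from_board.invert(),
        world_from_ct=world_from_ct,
        patientref_from_ct=ct_from_patientref.invert(),
        params=params,
    )


def simulated_ct_surface(
    phantom: PhantomModel,
    jitter_mm: float = 0.1,
    resolution_scale: float = 1.0,
    seed: int = 0,
) -> SurfaceMesh:
    """The pipeline's 'segmented CT' mesh: a (possibly decimated) regeneration
    of the true surface with seeded vertex jitter.

    ``resolution_scale = 1`` with ``jitter_mm = 0`` returns an exact copy of
    the ground-truth mesh.
    """
    params = phantom.params
    if resolution_scale != 1.0:
        params = replace(
            params,
            n_rings=max(3, int(round(params.n_rings * resolution_scale))),
            n_segments=max(6, int(round(params.n_segments * resolution_scale))),
        )
    mesh = _ellipsoid_face_mesh(params)
    if jitter_mm > 0:
        rng = derive_rng(seed, "ct-jitter")
        mesh = SurfaceMesh(
            mesh.vertices + rng.normal(scale=jitter_mm, size=mesh.vertices.shape),
            mesh.faces,
        )
    return mesh


def mesh_audit(mesh: SurfaceMesh) -> dict:
    """Connectivity/orientation audit used by the generator's tests.

    Returns edge-manifoldness, the number of boundary loops, and whether the
    (consistently wound) face normals point away from the origin.
    """
    edges = {}
    for face in mesh.faces:
        for i in range(3):
            e = (int(face[i]), int(face[(i + 1) % 3]))
            key = (min(e), max(e))
            edges.setdefault(key, []).append(e)
    boundary = [v[0] for v in edges.values() if len(v) == 1]
    manifold = all(len(v) <= 2 for v in edges.values())
    oriented = all(
        len(v) == 1 or (v[0][0] == v[1][1] and v[0][1] == v[1][0])
        for v in edges.values()
    )
    # walk boundary loops
    nxt = {e[0]: e[1] for e in boundary}
    loops = 0
    seen = set()
    for start in list(nxt):
        if start in seen:
            continue
        loops += 1
        cur = start
        while cur not in seen:
            seen.add(cur)
            cur = nxt.get(cur)
            if cur is None:
                loops = -1  # open chain: not a closed boundary
                break
        if loops < 0:
            break
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    outward = bool(
        np.all(np.einsum("fi,fi->f", mesh.face_normals(), centroids) > 0)
    )
    return {
        "edge_manifold": manifold,
        "consistently_oriented": oriented,
        "boundary_loops": loops,
        "normals_outward": outward,
    }


# ---------------------------------------------------------------------------
# Sensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """All simulated sensor-error magnitudes. Zero everywhere = ground truth.

    ``tracker_rot_deg`` is the *mean absolute* angular perturbation of a
    tracked body pose (axis uniform on the sphere); translational and pixel
    noises are per-axis Gaussian standard deviations.
    """

    corner_px: float = 0.5
    board_occlusion: float = 0.2
    depth_mm: float = 0.5
    depth_dropout: float = 0.1
    tracker_trans_mm: float = 0.35
    tracker_rot_deg: float = 0.1
    pointer_mm: float = 0.3
    handeye_rot_deg: float = 0.05
    handeye_trans_mm: float = 0.2
    ct_jitter_mm: float = 0.1
    prior_rot_deg: float = 5.0
    prior_trans_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("corner_px", "depth_mm", "tracker_trans_mm", "tracker_rot_deg",
                     "pointer_mm", "handeye_rot_deg", "handeye_trans_mm",
                     "ct_jitter_mm", "prior_rot_deg", "prior_trans_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("board_occlusion", "depth_dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseConfig":
        return cls(
            corner_px=0.0, board_occlusion=0.0, depth_mm=0.0, depth_dropout=0.0,
            tracker_trans_mm=0.0, tracker_rot_deg=0.0, pointer_mm=0.0,
            handeye_rot_deg=0.0, handeye_trans_mm=0.0, ct_jitter_mm=0.0,
            prior_rot_deg=0.0, prior_trans_mm=0.0, seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        return cls(**d)


def render_depth(
    target,
    camera_from_world: RigidTransform,
    intrinsics: CameraIntrinsics,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    z_near_mm: float = 1.0,
) -> DepthMap:
    """Z-buffer depth render of the phantom face (or any mesh in world frame).

    Perspective-correct interpolation of 1/z over each triangle equals the
    exact ray/plane intersection depth at the pixel centre, so the render is
    an exact ray cast. Requires distortion-free, zero-skew intrinsics (depth
    sensors emit rectified maps). Gaussian depth noise and Bernoulli dropout
    are applied to valid pixels when ``noise`` is given.
    """
    if intrinsics.has_distortion or intrinsics.skew != 0.0:
        raise ValueError("depth rendering requires zero distortion and zero skew")
    if isinstance(target, PhantomModel):
        mesh = target.face_mesh.transformed(target.world_from_ct)
    elif isinstance(target, SurfaceMesh):
        mesh = target
    else:
        raise TypeError("target must be a PhantomModel or SurfaceMesh")

    w, h = intrinsics.width, intrinsics.height
    zbuf = np.full((h, w), np.inf)
    vc = camera_from_world.apply(mesh.vertices)
    fx, fy, cx, cy = intrinsics.fx, intrinsics.fy, intrinsics.cx, intrinsics.cy

    for face in mesh.faces:
        tri = vc[face]
        if np.any(tri[:, 2] <= z_near_mm):
            continue
        u = fx * tri[:, 0] / tri[:, 2] + cx
        v = fy * tri[:, 1] / tri[:, 2] + cy
        u0 = max(int(np.ceil(u.min())), 0)
        u1 = min(int(np.floor(u.max())), w - 1)
        v0 = max(int(np.ceil(v.min())), 0)
        v1 = min(int(np.floor(v.max())), h - 1)
        if u0 > u1 or v0 > v1:
            continue
        det = (u[1] - u[0]) * (v[2] - v[0]) - (u[2] - u[0]) * (v[1] - v[0])
        if abs(det) < 1e-12:
            continue
        gu, gv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        du, dv = gu - u[0], gv - v[0]
        lam1 = (du * (v[2] - v[0]) - dv * (u[2] - u[0])) / det
        lam2 = (dv * (u[1] - u[0]) - du * (v[1] - v[0])) / det
        lam0 = 1.0 - lam1 - lam2
        inside = (lam0 >= -1e-12) & (lam1 >= -1e-12) & (lam2 >= -1e-12)
        if not inside.any():
            continue
        invz = lam0 / tri[0, 2] + lam1 / tri[1, 2] + lam2 / tri[2, 2]
        z = np.where(inside & (invz > 0), 1.0 / np.maximum(invz, 1e-300), np.inf)
        sub = zbuf[v0 : v1 + 1, u0 : u1 + 1]
        np.minimum(sub, z, out=sub)

    depth = np.where(np.isfinite(zbuf), zbuf, 0.0)
    if noise is not None and depth.any():
        rng = derive_rng(seed, "depth")
        valid = depth > 0
        if noise.depth_mm > 0:
            jitter = rng.normal(scale=noise.depth_mm, size=int(valid.sum()))
            depth[valid] = np.maximum(depth[valid] + jitter, 1e-3)
        if noise.depth_dropout > 0:
            drop = rng.random(int(valid.sum())) < noise.depth_dropout
            vals = depth[valid]
            vals[drop] = 0.0
            depth[valid] = vals
    return DepthMap(depth, intrinsics)


def observe_board(
    board: MarkerBoard,
    world_from_board: RigidTransform,
    camera_from_world: RigidTransform,
    intrinsics: CameraIntrinsics,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    frame: int = 0,
    camera_id: str = "cam",
) -> BoardDetection:
    """Simulated (noisy, partially occluded) detection of board points.

    Visible points are projected exactly, then ``round(occlusion * n)`` of
    them are dropped (seeded uniform choice) and per-coordinate Gaussian
    pixel noise is added. An empty detection (no points in view) is returned
    flagged, not raised.
    """
    from .camera import project

    pts_world = world_from_board.apply(board.points_3d)
    uv, visible = project(intrinsics, camera_from_world, pts_world)
    ids = board.point_ids[visible]
    uv = uv[visible]
    if noise is not None and len(ids):
        rng = derive_rng(seed, "board", camera_id, str(frame))
        if noise.board_occlusion > 0:
            n_drop = int(round(noise.board_occlusion * len(ids)))
            if n_drop >= len(ids):
                n_drop = len(ids) - min(len(ids), 1)
            keep = np.sort(rng.choice(len(ids), size=len(ids) - n_drop, replace=False))
            ids, uv = ids[keep], uv[keep]
        if noise.corner_px > 0:
            uv = uv + rng.normal(scale=noise.corner_px, size=uv.shape)
    return BoardDetection(frame=frame, camera_id=camera_id, point_ids=ids, pixels=uv)


def _perturb_pose(
    pose: RigidTransform, rot_deg_mean_abs: float, trans_mm: float,
    rng: np.random.Generator,
) -> RigidTransform:
    """Left-multiplied pose noise: rotation about the observer origin (so the
    positional error of a body grows with its distance — the lever-arm effect)
    plus isotropic Gaussian translation."""
    axis = rng.normal(size=3)
    axis /= max(np.linalg.norm(axis), 1e-12)
    angle = abs(rng.normal(scale=np.deg2rad(rot_deg_mean_abs) * np.sqrt(np.pi / 2.0)))
    dt = rng.normal(scale=trans_mm, size=3) if trans_mm > 0 else np.zeros(3)
    noise_pose = RigidTransform(Rotation.from_rotvec(axis * angle).as_matrix(), dt)
    return noise_pose.compose(pose)


def observe_tracker(
    phantom: PhantomModel,
    world_from_endoref: RigidTransform,
    world_from_tracker: RigidTransform,
    noise: NoiseConfig | None = None,
    frame: int = 0,
    seed: int = 0,
) -> TrackerFrame:
    """One noisy IR-tracker measurement of the patient and endoscope bodies."""
    tracker_from_world = world_from_tracker.invert()
    world_from_patientref = phantom.world_from_ct.compose(
        phantom.patientref_from_ct.invert()
    )
    t_pat = tracker_from_world.compose(world_from_patientref)
    t_endo = tracker_from_world.compose(world_from_endoref)
    if noise is not None and (noise.tracker_rot_deg > 0 or noise.tracker_trans_mm > 0):
        rng = derive_rng(seed, "tracker", str(frame))
        t_pat = _perturb_pose(t_pat, noise.tracker_rot_deg, noise.tracker_trans_mm, rng)
        t_endo = _perturb_pose(t_endo, noise.tracker_rot_deg, noise.tracker_trans_mm, rng)
    return TrackerFrame(
        frame=frame, tracker_from_patientref=t_pat, tracker_from_endoref=t_endo
    )


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_fixture_set(
    phantom: PhantomModel,
    out_dir,
    noise: NoiseConfig | None = None,
    board: MarkerBoard | None = None,
) -> None:
    """Write the phantom ground truth as the plain-text inputs the CLI reads."""
    from .fiducial_board import save_board_yaml
    from .meshio import save_ply, save_stl

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_ply(phantom.face_mesh, out / "face_mesh.ply")
    save_stl(phantom.face_mesh, out / "face_mesh.stl")
    pd.DataFrame(
        {
            "name": [f"target_{i}" for i in range(len(phantom.targets_ct))],
            "x_mm": phantom.targets_ct[:, 0],
            "y_mm": phantom.targets_ct[:, 1],
            "z_mm": phantom.targets_ct[:, 2],
        }
    ).to_csv(out / "targets.csv", index=False)
    pd.DataFrame(
        {
            "name": [f"fiducial_{int(i)}" for i in phantom.fiducials.ids],
            "x_mm": phantom.fiducials.points_ct[:, 0],
            "y_mm": phantom.fiducials.points_ct[:, 1],
            "z_mm": phantom.fiducials.points_ct[:, 2],
        }
    ).to_csv(out / "fiducials.csv", index=False)
    truth = {
        "board_from_ct": transform_to_dict(phantom.board_from_ct),
        "world_from_ct": transform_to_dict(phantom.world_from_ct),
        "patientref_from_ct": transform_to_dict(phantom.patientref_from_ct),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    if noise is not None:
        (out / "noise.yaml").write_text(yaml.safe_dump(noise.to_dict(), sort_keys=False))
    if board is not None:
        save_board_yaml(board, out / "board.yaml")
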