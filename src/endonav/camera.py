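"""Pinhole camera model with Brown-Conrady distortion, depth back-projection,
and planar-board calibration.

Intrinsic calibration follows the classic closed-form homography/absolute-conic
construction from multiple views of a planar grid, optionally followed by a
joint nonlinear refinement of intrinsics, distortion, and per-view poses.
Planar pose estimation (the per-frame board pose) uses a DLT homography in
undistorted normalized coordinates, orthonormalized and then refined against
the raw pixel observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import CalibrationError, DegenerateGeometryError, InvalidTransformError
from .geometry3d import RigidTransform, orthonormalize_rotation

__all__ = [
    "CameraIntrinsics",
    "DepthMap",
    "project",
    "backproject_depth",
    "distort_normalized",
    "undistort_normalized",
    "calibrate_intrinsics_zhang",
    "estimate_planar_pose",
    "homography_dlt",
    "save_intrinsics_json",
    "load_intrinsics_json",
    "save_depth_map",
    "load_depth_map",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics (px) plus 5-coefficient distortion (k1,k2,p1,p2,k3)."""

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    dist: np.ndarray = field(default_factory=lambda: np.zeros(5))
    width: int = 1920
    height: int = 1080

    def __post_init__(self):
        d = np.array(self.dist, dtype=float).reshape(-1)
        if d.size > 5:
            raise ValueError("at most 5 distortion coefficients (k1,k2,p1,p2,k3)")
        d = np.pad(d, (0, 5 - d.size))
        d.setflags(write=False)
        object.__setattr__(self, "dist", d)
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, self.skew, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def has_distortion(self) -> bool:
        return bool(np.any(self.dist != 0.0))


def distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply Brown-Conrady distortion to normalized image coordinates (N,2)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    k1, k2, p1, p2, k3 = np.pad(np.asarray(dist, float).reshape(-1), (0, 5))[:5]
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.column_stack([xd, yd])


def undistort_normalized(
    xy_d: np.ndarray, dist: np.ndarray, max_iter: int = 20, tol: float = 1e-10
) -> np.ndarray:
    """Invert the distortion by fixed-point iteration (<= 20 iters or 1e-10)."""
    xy_d = np.atleast_2d(np.asarray(xy_d, dtype=float))
    dist = np.asarray(dist, dtype=float)
    if not np.any(dist):
        return xy_d.copy()
    xy = xy_d.copy()
    for _ in range(max_iter):
        d = distort_normalized(xy, dist)
        step = xy_d - d
        xy = xy + step
        if np.abs(step).max() < tol:
            break
    return xy


def _pixels_to_normalized(intr: CameraIntrinsics, uv: np.ndarray) -> np.ndarray:
    """Pixels -> undistorted normalized coordinates."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    yd = (uv[:, 1] - intr.cy) / intr.fy
    xd = (uv[:, 0] - intr.cx - intr.skew * yd) / intr.fx
    return undistort_normalized(np.column_stack([xd, yd]), intr.dist)


def _normalized_to_pixels(intr: CameraIntrinsics, xy: np.ndarray) -> np.ndarray:
    d = distort_normalized(xy, intr.dist)
    u = intr.fx * d[:, 0] + intr.skew * d[:, 1] + intr.cx
    v = intr.fy * d[:, 1] + intr.cy
    return np.column_stack([u, v])


def project(
    intr: CameraIntrinsics,
    camera_from_world: RigidTransform,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Project world points to pixels.

    Returns ``(uv, visible)`` where ``uv`` is (N,2) pixel coordinates and
    ``visible`` flags points in front of the camera and inside the image.
    Out-of-view points get coordinates (possibly NaN behind the camera) but are
    flagged, never raised.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        return np.zeros((0, 2)), np.zeros(0, dtype=bool)
    pc = camera_from_world.apply(pts)
    z = pc[:, 2]
    front = z > 1e-9
    zsafe = np.where(front, z, np.nan)
    xy = pc[:, :2] / zsafe[:, None]
    uv = _normalized_to_pixels(intr, np.nan_to_num(xy, nan=0.0))
    uv = np.where(front[:, None], uv, np.nan)
    inside = (
        front
        & (uv[:, 0] >= 0)
        & (uv[:, 0] < intr.width)
        & (uv[:, 1] >= 0)
        & (uv[:, 1] < intr.height)
    )
    return uv, inside


@dataclass(frozen=True)
class DepthMap:
    """Dense depth image in mm; 0 marks invalid pixels."""

    depth: np.ndarray  # (H, W) float, mm
    intrinsics: CameraIntrinsics

    def __post_init__(self):
        d = np.array(self.depth, dtype=float)
        if d.ndim != 2:
            raise ValueError("depth must be a 2-D array")
        valid = d != 0
        if np.any(~np.isfinite(d)) or np.any(d[valid] <= 0):
            raise ValueError("valid depths must be strictly positive and finite")
        d.setflags(write=False)
        object.__setattr__(self, "depth", d)

    @property
    def height(self) -> int:
        return self.depth.shape[0]

    @property
    def width(self) -> int:
        return self.depth.shape[1]

    @property
    def valid_count(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def is_empty(self) -> bool:
        return self.valid_count == 0


def backproject_depth(depth_map: DepthMap):
    """Lift each valid depth pixel to a 3-D point in the camera frame.

    Pixel centres sit at integer coordinates. Returns a
    :class:`~endonav.registration.PointCloud` with one point per valid pixel.
    """
    from .registration import PointCloud  # local import avoids a cycle

    intr = depth_map.intrinsics
    rows, cols = np.nonzero(depth_map.depth)
    z = depth_map.depth[rows, cols]
    uv = np.column_stack([cols.astype(float), rows.astype(float)])
    xy = _pixels_to_normalized(intr, uv) if uv.size else np.zeros((0, 2))
    pts = np.column_stack([xy * z[:, None], z]) if z.size else np.zeros((0, 3))
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# Homography estimation
# ---------------------------------------------------------------------------

def _similarity_normalization(pts: np.ndarray) -> np.ndarray:
    """Hartley normalization: translate to centroid, scale mean radius to sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 1e-12 else 1.0
    return np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])


def _check_noncollinear(pts2d: np.ndarray, context: str) -> None:
    pts2d = np.asarray(pts2d, dtype=float)
    if pts2d.shape[0] < 4:
        raise DegenerateGeometryError(
            f"{context}: need >= 4 points, got {pts2d.shape[0]}"
        )
    sv = np.linalg.svd(pts2d - pts2d.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-12):
        raise DegenerateGeometryError(f"{context}: points are collinear")


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Planar homography H (3x3, H[2,2]=1) with dst ~ H @ src, via normalized DLT."""
    src = np.atleast_2d(np.asarray(src, dtype=float))[:, :2]
    dst = np.atleast_2d(np.asarray(dst, dtype=float))[:, :2]
    _check_noncollinear(src, "homography source")
    _check_noncollinear(dst, "homography destination")
    ts, td = _similarity_normalization(src), _similarity_normalization(dst)
    sh = (np.column_stack([src, np.ones(len(src))]) @ ts.T)[:, :2]
    dh = (np.column_stack([dst, np.ones(len(dst))]) @ td.T)[:, :2]
    n = len(src)
    a = np.zeros((2 * n, 9))
    x, y = sh[:, 0], sh[:, 1]
    u, v = dh[:, 0], dh[:, 1]
    a[0::2, 0], a[0::2, 1], a[0::2, 2] = -x, -y, -1.0
    a[0::2, 6], a[0::2, 7], a[0::2, 8] = u * x, u * y, u
    a[1::2, 3], a[1::2, 4], a[1::2, 5] = -x, -y, -1.0
    a[1::2, 6], a[1::2, 7], a[1::2, 8] = v * x, v * y, v
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("homography system is rank deficient")
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(td) @ h @ ts
    if abs(h[2, 2]) < 1e-15:
        raise DegenerateGeometryError("degenerate homography (h33 ~ 0)")
    return h / h[2, 2]


def _pose_from_homography(h: np.ndarray, board_xy: np.ndarray) -> RigidTransform:
    """Decompose a board->normalized-camera homography into a rigid pose.

    Sign is chosen so the board has positive mean depth in front of the camera
    (the physical branch of the two-fold planar ambiguity).
    """
    a1, a2, a3 = h[:, 0], h[:, 1], h[:, 2]
    lam = 2.0 / (np.linalg.norm(a1) + np.linalg.norm(a2))
    r1, r2, t = lam * a1, lam * a2, lam * a3
    r = orthonormalize_rotation(np.column_stack([r1, r2, np.cross(r1, r2)]))
    pose = RigidTransform(r, t)
    obj3 = np.column_stack([board_xy, np.zeros(len(board_xy))])
    if pose.apply(obj3)[:, 2].mean() < 0:
        r1, r2, t = -r1, -r2, -t
        r = orthonormalize_rotation(np.column_stack([r1, r2, np.cross(r1, r2)]))
        pose = RigidTransform(r, t)
    return pose


def _reprojection_residuals_rt(
    intr: CameraIntrinsics, r: np.ndarray, t: np.ndarray,
    obj3: np.ndarray, uv: np.ndarray,
) -> np.ndarray:
    # raw (R, t) variant: hot path inside optimizer loops
    pc = obj3 @ r.T + t
    xy = pc[:, :2] / pc[:, 2:3]
    return (_normalized_to_pixels(intr, xy) - uv).ravel()


def _reprojection_residuals(
    intr: CameraIntrinsics, pose: RigidTransform, obj3: np.ndarray, uv: np.ndarray
) -> np.ndarray:
    return _reprojection_residuals_rt(intr, pose.rotation, pose.translation, obj3, uv)


def estimate_planar_pose(
    intr: CameraIntrinsics,
    board_points_mm: np.ndarray,
    pixels: np.ndarray,
    refine: bool = True,
) -> tuple[RigidTransform, float]:
    """Pose of a planar point set (camera_from_board) from 2D-3D correspondences.

    ``board_points_mm`` are (N,2) in-plane coordinates (or (N,3) with z=0);
    ``pixels`` are the matching (N,2) observations. Returns the pose and the
    reprojection RMS in pixels (post-refinement when ``refine``).
    """
    obj = np.atleast_2d(np.asarray(board_points_mm, dtype=float))
    if obj.shape[1] == 3:
        if np.abs(obj[:, 2]).max(initial=0.0) > 1e-9:
            raise DegenerateGeometryError("board points must lie in the z=0 plane")
        obj = obj[:, :2]
    uv = np.atleast_2d(np.asarray(pixels, dtype=float))
    if obj.shape[0] != uv.shape[0]:
        raise ValueError("point/pixel count mismatch")
    _check_noncollinear(obj, "planar pose board points")
    if not np.all(np.isfinite(uv)):
        raise ValueError("non-finite pixel coordinates")

    xy = _pixels_to_normalized(intr, uv)
    h = homography_dlt(obj, xy)
    pose = _pose_from_homography(h, obj)

    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    res0 = _reprojection_residuals(intr, pose, obj3, uv)
    rms = float(np.sqrt(np.mean(res0**2)))
    if refine:
        x0 = np.concatenate(
            [Rotation.from_matrix(pose.rotation).as_rotvec(), pose.translation]
        )

        def fun(x):
            return _reprojection_residuals_rt(
                intr, Rotation.from_rotvec(x[:3]).as_matrix(), x[3:], obj3, uv
            )

        sol = least_squares(fun, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        rms_ref = float(np.sqrt(np.mean(sol.fun**2)))
        if rms_ref <= rms + 1e-12:  # refinement must never worsen the fit
            pose = RigidTransform(
                Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:]
            )
            rms = rms_ref
    return pose, rms


# ---------------------------------------------------------------------------
# Intrinsic calibration from planar views
# ---------------------------------------------------------------------------

def _vij(h: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ]
    )


def _intrinsics_closed_form(hs: list[np.ndarray], image_size) -> CameraIntrinsics:
    v = []
    for h in hs:
        v.append(_vij(h, 0, 1))
        v.append(_vij(h, 0, 0) - _vij(h, 1, 1))
    v = np.asarray(v)
    _, s, vt = np.linalg.svd(v)
    if len(hs) >= 3 and s[-1] > 0.5 * s[-2]:
        raise CalibrationError(
            "degenerate view set: homography constraints do not isolate the "
            "image of the absolute conic (views may be related by pure translation)"
        )
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12 * b12
    if abs(denom) < 1e-18 or abs(b11) < 1e-18:
        raise CalibrationError("degenerate view set: conic system is singular")
    v0 = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13 * b13 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0 or lam * b11 / denom <= 0:
        raise CalibrationError("degenerate view set: negative focal-length estimate")
    alpha = np.sqrt(lam / b11)
    beta = np.sqrt(lam * b11 / denom)
    gamma = -b12 * alpha * alpha * beta / lam
    u0 = gamma * v0 / beta - b13 * alpha * alpha / lam
    w, hgt = image_size
    return CameraIntrinsics(
        fx=float(alpha), fy=float(beta),
        cx=float(np.clip(u0, 0, w - 1)), cy=float(np.clip(v0, 0, hgt - 1)),
        skew=float(gamma), width=w, height=hgt,
    )


def calibrate_intrinsics_zhang(
    board,
    detections,
    refine: bool = True,
    image_size: tuple[int, int] = (1920, 1080),
) -> tuple[CameraIntrinsics, list[float]]:
    """Intrinsic calibration from >= 3 views of a planar board.

    ``board`` is a :class:`~endonav.fiducial_board.MarkerBoard`; ``detections``
    is a list of :class:`~endonav.fiducial_board.BoardDetection`, one per view.
    Returns the intrinsics and per-view reprojection RMS (px), reported with
    the final (refined, if requested) parameters.

    Raises :class:`CalibrationError` for fewer than 3 usable views or a
    degenerate view set.
    """
    views = []
    for det in detections:
        obj, uv = board.match_detection(det)
        try:
            _check_noncollinear(obj, "calibration view")
        except DegenerateGeometryError:
            continue
        views.append((obj, uv))
    if len(views) < 3:
        raise CalibrationError(
            f"need >= 3 usable views with >= 4 non-collinear points, got {len(views)}"
        )

    hs = [homography_dlt(obj, uv) for obj, uv in views]
    intr = _intrinsics_closed_form(hs, image_size)
    kinv = np.linalg.inv(intr.K)
    poses = [_pose_from_homography(kinv @ h, obj) for h, (obj, _) in zip(hs, views)]

    obj3s = [np.column_stack([obj, np.zeros(len(obj))]) for obj, _ in views]
    uvs = [uv for _, uv in views]

    if refine:
        x0 = [intr.fx, intr.fy, intr.cx, intr.cy, intr.skew, 0, 0, 0, 0, 0]
        for p in poses:
            x0.extend(Rotation.from_matrix(p.rotation).as_rotvec())
            x0.extend(p.translation)
        x0 = np.asarray(x0, dtype=float)

        def unpack(x):
            ci = CameraIntrinsics(
                fx=x[0], fy=x[1],
                cx=float(np.clip(x[2], 0, image_size[0] - 1e-6)),
                cy=float(np.clip(x[3], 0, image_size[1] - 1e-6)),
                skew=x[4], dist=x[5:10],
                width=image_size[0], height=image_size[1],
            )
            ps = []
            for i in range(len(views)):
                seg = x[10 + 6 * i : 16 + 6 * i]
                ps.append(
                    RigidTransform(Rotation.from_rotvec(seg[:3]).as_matrix(), seg[3:])
                )
            return ci, ps

        def fun(x):
            ci, ps = unpack(x)
            return np.concatenate(
                [
                    _reprojection_residuals(ci, p, o3, uv)
                    for p, o3, uv in zip(ps, obj3s, uvs)
                ]
            )

        sol = least_squares(fun, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        intr, poses = unpack(sol.x)

    rms = [
        float(np.sqrt(np.mean(_reprojection_residuals(intr, p, o3, uv) ** 2)))
        for p, o3, uv in zip(poses, obj3s, uvs)
    ]
    return intr, rms


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def intrinsics_to_dict(intr: CameraIntrinsics) -> dict:
    return {
        "units": "px",
        "fx": intr.fx, "fy": intr.fy, "cx": intr.cx, "cy": intr.cy,
        "skew": intr.skew, "dist": [float(d) for d in intr.dist],
        "width": intr.width, "height": intr.height,
    }


def intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    if d.get("units") != "px":
        raise ValueError(f"intrinsics units must be 'px', got {d.get('units')!r}")
    return CameraIntrinsics(
        fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
        skew=d.get("skew", 0.0), dist=np.asarray(d.get("dist", []), dtype=float),
        width=int(d["width"]), height=int(d["height"]),
    )


def save_intrinsics_json(intr: CameraIntrinsics, path) -> None:
    Path(path).write_text(json.dumps(intrinsics_to_dict(intr), indent=2))


def load_intrinsics_json(path) -> CameraIntrinsics:
    return intrinsics_from_dict(json.loads(Path(path).read_text()))


def save_depth_map(dm: DepthMap, png_path, scale_mm: float | None = None) -> None:
    """Write a depth map as a 16-bit grayscale PNG plus a JSON sidecar.

    ``scale_mm`` is millimetres per integer unit; when omitted it is chosen to
    span the full 16-bit range. The integer grid round-trips bit-exactly.
    """
    from PIL import Image

    png_path = Path(png_path)
    if scale_mm is None:
        dmax = float(dm.depth.max(initial=0.0))
        scale_mm = max(dmax / 65535.0, 1e-6)
    grid = np.round(dm.depth / scale_mm)
    if grid.max(initial=0.0) > 65535:
        raise ValueError("depth exceeds 16-bit range at the given scale")
    Image.fromarray(grid.astype(np.uint16)).save(png_path)
    sidecar = {
        "units": "mm",
        "scale_mm_per_unit": scale_mm,
        "width": dm.width,
        "height": dm.height,
        "intrinsics": intrinsics_to_dict(dm.intrinsics),
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_depth_map(png_path) -> DepthMap:
    from PIL import Image

    png_path = Path(png_path)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    if meta.get("units") != "mm":
        raise ValueError("depth sidecar must declare units 'mm'")
    grid = np.asarray(Image.open(png_path), dtype=np.float64)
    return DepthMap(grid * meta["scale_mm_per_unit"], intrinsics_from_dict(meta["intrinsics"]))
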