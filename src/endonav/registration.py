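"""Surface and landmark registration.

The automatic pipeline aligns a depth-reconstructed face cloud to the
segmented CT surface: a pose prior provides the initial alignment, then a
robust point-to-plane ICP with a Tukey biweight kernel and a correspondence
distance gate refines it. The comparator pipeline uses closed-form rigid
landmark alignment (Procrustes / Arun's SVD method).

ICP scale handling
------------------
The configured Tukey scale (default k = 0.1 mm) and distance gate (default
1 mm) are far tighter than a coarse initial alignment, so a fixed gate would
reject every correspondence at the first iteration. The solver therefore
anneals both scales: at each iteration the effective gate is
``max(gate, 3 * median NN distance)`` and the effective kernel scale is
``max(k, 6 * median |residual|)``. As the alignment converges both collapse
to their configured values, so the final iterations use exactly the
configured kernel and gate. Setting ``adaptive=False`` disables this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InsufficientDataError, NoOverlapError
from .geometry3d import RigidTransform, orthonormalize_rotation

__all__ = [
    "PointCloud",
    "SurfaceMesh",
    "ICPConfig",
    "RegistrationResult",
    "estimate_normals",
    "initial_align_from_prior",
    "icp_point_to_plane_robust",
    "procrustes_register",
    "compose_ct_to_reference",
    "tukey_weight",
    "sample_surface",
    "MeshProximity",
    "save_landmarks_csv",
    "load_landmarks_csv",
]


@dataclass(frozen=True)
class PointCloud:
    """N x 3 points (mm) with optional unit normals."""

    points: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self):
        pts = np.array(self.points, dtype=float).reshape(-1, 3)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.normals is not None:
            nrm = np.array(self.normals, dtype=float).reshape(-1, 3)
            if nrm.shape != pts.shape:
                raise ValueError("normals must match points shape")
            lengths = np.linalg.norm(nrm, axis=1)
            if lengths.size and np.abs(lengths - 1.0).max() > 1e-6:
                raise ValueError("normals must be unit length (within 1e-6)")
            nrm.setflags(write=False)
            object.__setattr__(self, "normals", nrm)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "PointCloud":
        nrm = None if self.normals is None else self.normals @ t.rotation.T
        return PointCloud(t.apply(self.points) if len(self) else self.points, nrm)


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangle mesh: V x 3 vertices (mm), F x 3 integer faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.array(self.vertices, dtype=float).reshape(-1, 3)
        f = np.array(self.faces, dtype=np.int64).reshape(-1, 3)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        lengths = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(lengths, 1e-300)

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def transformed(self, t: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(t.apply(self.vertices), self.faces)

    def as_cloud(self) -> PointCloud:
        return PointCloud(self.vertices)


@dataclass(frozen=True)
class ICPConfig:
    """Settings for the robust point-to-plane ICP."""

    kernel: str = "tukey"  # "tukey" or "none" (plain least squares)
    k_mm: float = 0.1  # Tukey scale
    max_correspondence_mm: float = 1.0  # distance gate
    max_iterations: int = 50
    rel_tol: float = 1e-8  # relative cost-change convergence tolerance
    normal_k: int = 10  # k-NN neighbourhood for normal estimation
    adaptive: bool = True  # anneal gate/scale from the coarse regime
    plateau_window: int = 4  # iterations of flat cost that count as converged
    plateau_tol: float = 1e-3  # relative cost spread defining "flat" (noisy data)

    def __post_init__(self):
        if self.kernel not in ("tukey", "none"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.k_mm <= 0 or self.max_correspondence_mm <= 0:
            raise ValueError("k and distance threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform  # target_from_source
    iterations: int
    final_cost: float
    inlier_count: int
    inlier_rms_mm: float
    converged: bool

    def __post_init__(self):
        if self.inlier_rms_mm < 0:
            raise ValueError("RMS must be >= 0")


def tukey_weight(r: np.ndarray, k: float) -> np.ndarray:
    """Tukey biweight: (1 - (r/k)^2)^2 for |r| <= k, else 0."""
    r = np.asarray(r, dtype=float)
    u = r / k
    w = (1.0 - u * u) ** 2
    return np.where(np.abs(u) <= 1.0, w, 0.0)


def _tukey_rho(r: np.ndarray, k: float) -> np.ndarray:
    u = np.clip((r / k) ** 2, 0.0, 1.0)
    # expanded form of (k^2/6) (1 - (1-u)^3): no cancellation for tiny u
    return (k * k / 6.0) * u * (3.0 - 3.0 * u + u * u)


def estimate_normals(
    cloud: PointCloud, k_neighbors: int = 10, viewpoint=(0.0, 0.0, 0.0)
) -> PointCloud:
    """Per-point normals from k-NN PCA, oriented toward ``viewpoint``.

    The normal is the smallest principal axis of the neighbourhood covariance;
    its sign is flipped so it points toward the sensor origin.
    """
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    pts = cloud.points
    if len(pts) < k_neighbors:
        raise InsufficientDataError(
            f"need at least k_neighbors={k_neighbors} points, got {len(pts)}"
        )
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_neighbors)
    nbrs = pts[idx]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue axis
    to_view = np.asarray(viewpoint, dtype=float) - pts
    flip = np.einsum("ni,ni->n", normals, to_view) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts, normals)


def initial_align_from_prior(ct_surface, prior: RigidTransform):
    """Move the CT surface by the pose prior; this is the ICP starting state.

    Accepts a :class:`SurfaceMesh` or :class:`PointCloud` and returns the same
    kind with transformed coordinates. The caller keeps ``prior`` so the final
    registration can be reported in the original CT frame.
    """
    return ct_surface.transformed(prior)


# ---------------------------------------------------------------------------
# Closest point on a triangle mesh
# ---------------------------------------------------------------------------

def _closest_point_on_triangles(p, a, b, c):
    """Closest points on triangles (a,b,c) to query points p; all (..., 3).

    Vectorized region-based algorithm (Ericson, Real-Time Collision
    Detection, 5.1.5).
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d4 * d5

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    v_ab = np.nan_to_num(v_ab)[..., None]
    w_ac = np.nan_to_num(w_ac)[..., None]
    w_bc = np.nan_to_num(w_bc)[..., None]
    v_in = np.nan_to_num(v_in)[..., None]
    w_in = np.nan_to_num(w_in)[..., None]

    out = a + ab * v_in + ac * w_in  # interior (default)
    m = ((d4 - d3 >= 0) & (d5 - d6 >= 0) & (va <= 0))[..., None]
    out = np.where(m, b + w_bc * (c - b), out)
    m = ((d2 >= 0) & (d6 <= 0) & (vb <= 0))[..., None]
    out = np.where(m, a + w_ac * ac, out)
    m = ((d1 >= 0) & (d3 <= 0) & (vc <= 0))[..., None]
    out = np.where(m, a + v_ab * ab, out)
    m = ((d6 >= 0) & (d5 <= d6))[..., None]
    out = np.where(m, c, out)
    m = ((d3 >= 0) & (d4 <= d3))[..., None]
    out = np.where(m, b, out)
    m = ((d1 <= 0) & (d2 <= 0))[..., None]
    out = np.where(m, a, out)
    return out


class MeshProximity:
    """Exact closest-point queries against a triangle mesh.

    Candidate faces come from a KD-tree over face centroids (k nearest) and
    the exact point-triangle distance picks the best. The k-NN answer is
    provably exact whenever the k-th centroid lies beyond
    ``best_distance + max_face_radius``; the few points failing that bound
    fall back to a ball query of the same radius, which cannot miss.
    """

    def __init__(self, mesh: SurfaceMesh, k_candidates: int = 30):
        if mesh.n_faces == 0:
            raise InsufficientDataError("mesh has no faces")
        self.mesh = mesh
        self.k = min(k_candidates, mesh.n_faces)
        v, f = mesh.vertices, mesh.faces
        self._tri = (v[f[:, 0]], v[f[:, 1]], v[f[:, 2]])
        centroids = (self._tri[0] + self._tri[1] + self._tri[2]) / 3.0
        self._tree = cKDTree(centroids)
        self._normals = mesh.face_normals()
        self._face_radius = float(
            max(
                np.linalg.norm(t - centroids, axis=1).max() for t in self._tri
            )
        )

    def _exact_over(self, p: np.ndarray, cand: np.ndarray):
        a, b, c = (t[cand] for t in self._tri)
        closest = _closest_point_on_triangles(p[..., None, :], a, b, c)
        diff = closest - p[..., None, :]
        d2 = np.einsum("...ki,...ki->...k", diff, diff)
        best = np.argmin(d2, axis=-1)
        return closest, d2, best

    def query(self, points: np.ndarray):
        """Return (closest_points, face_normals, distances) for each query."""
        points = np.atleast_2d(points)
        dc, cand = self._tree.query(points, k=self.k)
        dc, cand = np.atleast_2d(dc), np.atleast_2d(cand)
        closest, d2, best = self._exact_over(points, cand)
        rows = np.arange(len(points))
        out_pts = closest[rows, best]
        out_d = np.sqrt(d2[rows, best])
        out_faces = cand[rows, best]

        # rigorous optimality check; fall back to a ball query where needed.
        # Restricted to near-surface points: far points are gated or
        # down-weighted by ICP, so approximate distances suffice there.
        unsure = np.nonzero(
            (self.k < self.mesh.n_faces)
            & (dc[:, -1] < out_d + self._face_radius)
            & (out_d < self._face_radius)
        )[0]
        if unsure.size:
            balls = self._tree.query_ball_point(
                points[unsure], out_d[unsure] + self._face_radius + 1e-12
            )
            width = max((len(b) for b in balls), default=0)
            if width:
                cand2 = np.zeros((len(unsure), width), dtype=np.int64)
                for j, b in enumerate(balls):  # pad with the first candidate
                    cand2[j, : len(b)] = b
                    cand2[j, len(b):] = b[0] if b else out_faces[unsure[j]]
                cp, bd2, bb = self._exact_over(points[unsure], cand2)
                jrows = np.arange(len(unsure))
                better = bd2[jrows, bb] < out_d[unsure] ** 2
                upd = unsure[better]
                out_pts[upd] = cp[jrows, bb][better]
                out_d[upd] = np.sqrt(bd2[jrows, bb][better])
                out_faces[upd] = cand2[jrows, bb][better]
        return out_pts, self._normals[out_faces], out_d


# ---------------------------------------------------------------------------
# Robust point-to-plane ICP
# ---------------------------------------------------------------------------

class _CloudTarget:
    def __init__(self, cloud: PointCloud):
        if cloud.normals is None:
            raise ValueError("target cloud must carry normals (estimate_normals)")
        self._tree = cKDTree(cloud.points)
        self._points = cloud.points
        self._normals = cloud.normals

    def query(self, points):
        d, idx = self._tree.query(points)
        return self._points[idx], self._normals[idx], d


def icp_point_to_plane_robust(
    source: PointCloud,
    target,
    config: ICPConfig = ICPConfig(),
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Robust point-to-plane ICP; returns target_from_source.

    ``target`` is a :class:`PointCloud` with normals or a
    :class:`SurfaceMesh` (closest-point-on-surface correspondences with face
    normals). Each iteration: nearest correspondences, distance gating, Tukey
    weighting of the point-to-plane residuals, and a weighted small-angle
    linearized solve, with the rotation re-orthonormalized by polar
    decomposition.

    Raises :class:`NoOverlapError` (carrying the last transform) if gating
    leaves zero correspondences.
    """
    if len(source) < 6:
        raise InsufficientDataError("source needs >= 6 points for a 6-DoF solve")
    lookup = MeshProximity(target) if isinstance(target, SurfaceMesh) else _CloudTarget(target)

    t = RigidTransform.identity() if init is None else init
    prev_cost = None
    cost = np.inf
    converged = False
    inlier_count = 0
    inlier_rms = 0.0
    iterations = 0
    history: list[float] = []

    for iterations in range(1, config.max_iterations + 1):
        moved = t.apply(source.points)
        q, n, d = lookup.query(moved)

        gate = config.max_correspondence_mm
        if config.adaptive:
            gate = max(gate, 3.0 * float(np.median(d)))
        keep = d <= gate
        if not np.any(keep):
            raise NoOverlapError(
                f"no correspondences within {gate:.3g} mm at iteration {iterations}",
                last_transform=t,
            )
        p, q, n = moved[keep], q[keep], n[keep]
        r = np.einsum("ni,ni->n", n, p - q)

        k = config.k_mm
        if config.kernel == "tukey":
            if config.adaptive:
                k = max(k, 6.0 * float(np.median(np.abs(r))))
            w = tukey_weight(r, k)
            cost = float(np.mean(_tukey_rho(r, k)))
        else:
            w = np.ones_like(r)
            cost = float(np.mean(r * r))

        if w.sum() < 1e-12:  # kernel rejected everything; treat as no overlap
            raise NoOverlapError(
                "all correspondences received zero robust weight", last_transform=t
            )

        inlier = w > 0
        inlier_count = int(np.count_nonzero(inlier))
        inlier_rms = float(np.sqrt(np.mean(r[inlier] ** 2)))

        # weighted linearized solve: rows [p x n, n] . [omega, dt] = -r
        a = np.hstack([np.cross(p, n), n])
        sw = np.sqrt(w)
        x, *_ = np.linalg.lstsq(a * sw[:, None], -r * sw, rcond=None)
        omega, dt = x[:3], x[3:]
        step = RigidTransform(
            orthonormalize_rotation(Rotation.from_rotvec(omega).as_matrix()), dt
        )
        t = step.compose(t)

        small_step = np.linalg.norm(omega) < 1e-12 and np.linalg.norm(dt) < 1e-12
        history.append(cost)
        plateau = False
        if len(history) >= config.plateau_window:
            win = history[-config.plateau_window:]
            plateau = (max(win) - min(win)) <= config.plateau_tol * max(
                abs(max(win)), 1e-300
            )
        if small_step or plateau:
            converged = True
            break
        if prev_cost is not None:
            rel = abs(prev_cost - cost) / max(prev_cost, 1e-300)
            if rel < config.rel_tol:
                converged = True
                break
        prev_cost = cost

    return RegistrationResult(
        transform=t,
        iterations=iterations,
        final_cost=cost,
        inlier_count=inlier_count,
        inlier_rms_mm=inlier_rms,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Closed-form landmark registration
# ---------------------------------------------------------------------------

def procrustes_register(
    source_points: np.ndarray, target_points: np.ndarray
) -> tuple[RigidTransform, float]:
    """Rigid alignment of corresponding point sets (Arun's SVD method).

    Minimizes sum ||T s_i - t_i||^2 in closed form, with the reflection guard
    on the smallest singular direction. Returns the transform and the FRE
    (RMS residual after alignment, mm).
    """
    s = np.atleast_2d(np.asarray(source_points, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_points, dtype=float))
    if s.shape != tgt.shape or s.shape[1] != 3:
        raise ValueError("source and target must both be (K, 3)")
    if s.shape[0] < 3:
        raise InsufficientDataError("need >= 3 corresponding points")
    for pts, name in ((s, "source"), (tgt, "target")):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1e-12):
            raise DegenerateGeometryError(f"{name} points are collinear")

    cs, ct = s.mean(axis=0), tgt.mean(axis=0)
    h = (s - cs).T @ (tgt - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - r @ cs
    pose = RigidTransform(orthonormalize_rotation(r), t)
    fre = float(np.sqrt(np.mean(np.sum((pose.apply(s) - tgt) ** 2, axis=1))))
    return pose, fre


def compose_ct_to_reference(
    camera_from_ct: RigidTransform,
    camera_from_board_at_registration: RigidTransform,
) -> RigidTransform:
    """Persist the registration on the board: board_from_ct.

    ``board_from_ct = inv(camera_from_board) o camera_from_ct`` — after this,
    the board is the sole patient reference.
    """
    return camera_from_board_at_registration.invert().compose(camera_from_ct)


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def sample_surface(
    mesh: SurfaceMesh, n: int, seed: int | np.random.Generator = 0,
    with_normals: bool = False,
) -> PointCloud:
    """Area-weighted uniform sampling of points on the mesh surface."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise DegenerateGeometryError("mesh has zero surface area")
    faces = rng.choice(mesh.n_faces, size=n, p=areas / total)
    u, v = rng.random(n), rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    a = mesh.vertices[mesh.faces[faces, 0]]
    b = mesh.vertices[mesh.faces[faces, 1]]
    c = mesh.vertices[mesh.faces[faces, 2]]
    pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    if with_normals:
        return PointCloud(pts, mesh.face_normals()[faces])
    return PointCloud(pts)


def save_landmarks_csv(names, points_mm: np.ndarray, path) -> None:
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    pd.DataFrame(
        {"name": list(names), "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2]}
    ).to_csv(path, index=False)


def load_landmarks_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return df["name"].astype(str).tolist(), df[["x_mm", "y_mm", "z_mm"]].to_numpy()
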