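"""SE(3) rigid-transform algebra — the currency of every pose chain here.

Conventions
-----------
* Rotations are stored as 3x3 orthonormal matrices with determinant +1.
* All translations (and every other length in this package) are millimetres.
* Point sets are row-per-point ``(N, 3)`` arrays; ``apply`` maps each row
  ``x`` to ``R @ x + t``.
* ``a.compose(b)`` (also ``a @ b``) first applies ``b``, then ``a``:
  ``compose(a, b).apply(x) == a.apply(b.apply(x))``.

Serialization uses a 4x4 homogeneous-matrix JSON schema with an explicit
``"units": "mm"`` field; the reader rejects any other unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidTransformError

__all__ = [
    "RigidTransform",
    "compose",
    "invert",
    "apply",
    "pose_error",
    "random_pose",
    "orthonormalize_rotation",
    "look_at",
    "save_transform_json",
    "load_transform_json",
]

#: Per-entry tolerance for the orthonormality / determinant invariants.
ORTHONORMAL_TOL = 1e-9


def orthonormalize_rotation(m: np.ndarray) -> np.ndarray:
    """Project a near-rotation 3x3 matrix onto SO(3) (polar decomposition).

    Returns the closest rotation in the Frobenius sense, with det +1 enforced
    by flipping the sign of the smallest singular direction.
    """
    m = np.asarray(m, dtype=float)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (proper) transform of 3-space: rotation then translation."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.array(self.rotation, dtype=float)
        t = np.array(self.translation, dtype=float).reshape(-1)
        if r.shape != (3, 3):
            raise InvalidTransformError(f"rotation must be 3x3, got {r.shape}")
        if t.shape != (3,):
            raise InvalidTransformError(f"translation must be length 3, got {t.shape}")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise InvalidTransformError("non-finite entries in transform")
        err = np.abs(r.T @ r - np.eye(3)).max()
        if err > ORTHONORMAL_TOL:
            raise InvalidTransformError(
                f"rotation is not orthonormal (max |R^T R - I| = {err:.3e})"
            )
        det = np.linalg.det(r)
        if abs(det - 1.0) > ORTHONORMAL_TOL:
            raise InvalidTransformError(f"rotation determinant {det:.12f} != +1")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix; bottom row must be [0,0,0,1]."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise InvalidTransformError(f"bottom row must be [0,0,0,1], got {m[3]}")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle rotation vector in degrees plus a translation (mm)."""
        rv = np.deg2rad(np.asarray(rotvec_deg, dtype=float))
        return cls(Rotation.from_rotvec(rv).as_matrix(), np.asarray(translation, float))

    # -- core algebra ------------------------------------------------------
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    __matmul__ = compose

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (row-per-point ``(N, 3)`` or a single ``(3,)``) by R x + t."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[-1] != 3:
            raise InvalidTransformError(f"points must be (N, 3), got {pts.shape}")
        if pts.size and not np.all(np.isfinite(pts)):
            raise InvalidTransformError("non-finite point coordinates")
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.rad2deg(Rotation.from_matrix(self.rotation).magnitude()))

    def __repr__(self):  # compact, matrix dumps are noisy in test output
        rv = Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)
        return (
            f"RigidTransform(rotvec_deg=[{rv[0]:.4g}, {rv[1]:.4g}, {rv[2]:.4g}], "
            f"t_mm=[{self.translation[0]:.4g}, {self.translation[1]:.4g}, "
            f"{self.translation[2]:.4g}])"
        )


# -- module-level functional forms (mirror the method API) -----------------

def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def apply(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    return t.apply(points)


def pose_error(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """Angular (degrees) and translational (mm) distance between two poses.

    Rotation error is the angle of the relative rotation ``a.R^T b.R``;
    translation error is the Euclidean norm of the translation difference.
    """
    rel = a.rotation.T @ b.rotation
    ang = float(np.rad2deg(Rotation.from_matrix(orthonormalize_rotation(rel)).magnitude()))
    return ang, float(np.linalg.norm(a.translation - b.translation))


def random_pose(
    seed: int | np.random.Generator,
    max_rotation_deg: float,
    max_translation_mm: float,
) -> RigidTransform:
    """Deterministic random pose with bounded rotation angle and translation norm.

    The rotation axis and translation direction are uniform on the sphere;
    the rotation angle is uniform on [0, max] and the translation magnitude is
    sampled so that points are uniform in the ball of the given radius.
    """
    if max_rotation_deg < 0 or max_translation_mm < 0:
        raise ValueError("bounds must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])
    angle = np.deg2rad(max_rotation_deg) * rng.random()
    rot = Rotation.from_rotvec(axis * angle).as_matrix()

    direction = rng.normal(size=3)
    n = np.linalg.norm(direction)
    direction = direction / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])
    radius = max_translation_mm * rng.random() ** (1.0 / 3.0)
    return RigidTransform(rot, direction * radius)


def look_at(eye, target, up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """Camera pose (camera_from_world) with +z pointing from ``eye`` to ``target``.

    Camera axes follow the usual image convention: +z forward, x/y spanning
    the image plane (right-handed).
    """
    eye = np.asarray(eye, dtype=float)
    z = np.asarray(target, dtype=float) - eye
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("eye and target coincide")
    z /= nz
    up = np.asarray(up, dtype=float)
    x = np.cross(up, z)
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("up direction is parallel to the viewing direction")
    x /= nx
    y = np.cross(z, x)
    r_world_cam = np.column_stack([x, y, z])  # columns: camera axes in world
    return RigidTransform(r_world_cam.T, -r_world_cam.T @ eye)


# -- JSON serialization ----------------------------------------------------

def transform_to_dict(t: RigidTransform) -> dict:
    return {"units": "mm", "matrix": t.matrix().tolist()}


def transform_from_dict(d: dict) -> RigidTransform:
    if d.get("units") != "mm":
        raise InvalidTransformError(
            f"transform units must be 'mm', got {d.get('units')!r}"
        )
    return RigidTransform.from_matrix(np.asarray(d["matrix"], dtype=float))


def save_transform_json(t: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=2))


def load_transform_json(path) -> RigidTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))
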