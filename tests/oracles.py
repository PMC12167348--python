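"""Independent reference implementations used as oracles.

These deliberately re-derive results through different code paths than the
package (scalar loops, generic optimizers, brute-force enumeration) so that
agreement is meaningful.
"""

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


def distort_point_scalar(x, y, k1=0.0, k2=0.0, p1=0.0, p2=0.0, k3=0.0):
    """Textbook Brown-Conrady distortion, one point at a time."""
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return xd, yd


def project_point_scalar(intr, rotation, translation, point):
    """Scalar pinhole projection with distortion (independent of camera.py)."""
    pc = rotation @ np.asarray(point) + translation
    x, y = pc[0] / pc[2], pc[1] / pc[2]
    k1, k2, p1, p2, k3 = intr.dist
    xd, yd = distort_point_scalar(x, y, k1, k2, p1, p2, k3)
    return np.array([intr.fx * xd + intr.skew * yd + intr.cx,
                     intr.fy * yd + intr.cy])


def brute_force_rigid_fit(source, target, x0=None):
    """Nonlinear minimization of sum ||R s + t - q||^2 over (rotvec, t).

    Returns (rotation, translation, rms_residual). Generic optimizer route,
    independent of the closed-form SVD solution.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if x0 is None:
        x0 = np.zeros(6)
        x0[3:] = target.mean(axis=0) - source.mean(axis=0)

    def residuals(x):
        r = Rotation.from_rotvec(x[:3]).as_matrix()
        return (source @ r.T + x[3:] - target).ravel()

    sol = least_squares(residuals, x0, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    r = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    rms = float(np.sqrt(np.mean(np.sum((source @ r.T + sol.x[3:] - target) ** 2, axis=1))))
    return r, sol.x[3:], rms


def plain_point_to_plane_icp(source_pts, target_pts, target_normals,
                             init_rotation=None, init_translation=None,
                             iterations=60):
    """Unweighted point-to-plane ICP, no gating, no robust kernel.

    Small independent implementation used to cross-check the package's robust
    solver on clean data. Returns (rotation, translation).
    """
    r = np.eye(3) if init_rotation is None else np.array(init_rotation, float)
    t = np.zeros(3) if init_translation is None else np.array(init_translation, float)
    tree = cKDTree(target_pts)
    for _ in range(iterations):
        moved = source_pts @ r.T + t
        _, idx = tree.query(moved)
        q = target_pts[idx]
        n = target_normals[idx]
        resid = np.sum(n * (moved - q), axis=1)
        a = np.hstack([np.cross(moved, n), n])
        x, *_ = np.linalg.lstsq(a, -resid, rcond=None)
        dr = Rotation.from_rotvec(x[:3]).as_matrix()
        r = dr @ r
        t = dr @ t + x[3:]
        if np.linalg.norm(x) < 1e-14:
            break
    return r, t


def rotation_angle_deg(r_a, r_b):
    return float(np.rad2deg(Rotation.from_matrix(r_a.T @ r_b).magnitude()))
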