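"""The comparator system: an IR tracker observing a patient-reference body and
an endoscope-reference body, pointer-sampled fiducial registration, and the
dual-reference overlay chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraIntrinsics, project
from .errors import InsufficientDataError
from .geometry3d import RigidTransform
from .registration import procrustes_register

__all__ = [
    "TrackerFrame",
    "FiducialSet",
    "OverlayResult",
    "sample_fiducials_with_pointer",
    "register_ir",
    "ir_overlay_chain",
    "save_tracker_log_csv",
    "load_tracker_log_csv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackerFrame:
    """One tracker measurement; an invalid body carries no transform (None)."""

    frame: int
    tracker_from_patientref: RigidTransform | None
    tracker_from_endoref: RigidTransform | None

    @property
    def patientref_valid(self) -> bool:
        return self.tracker_from_patientref is not None

    @property
    def endoref_valid(self) -> bool:
        return self.tracker_from_endoref is not None


@dataclass(frozen=True)
class FiducialSet:
    """Identified fiducial points in the CT frame (the physical setup uses 7)."""

    ids: np.ndarray  # (K,) int
    points_ct: np.ndarray  # (K, 3) mm

    def __post_init__(self):
        ids = np.array(self.ids, dtype=int)
        pts = np.array(self.points_ct, dtype=float).reshape(-1, 3)
        if len(ids) != len(pts):
            raise ValueError("ids and points must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("fiducial ids must be unique")
        if len(ids) < 3:
            raise InsufficientDataError("need >= 3 fiducials")
        ids.setflags(write=False)
        pts.setflags(write=False)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "points_ct", pts)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class OverlayResult:
    """Outcome of projecting targets through an overlay chain for one frame."""

    status: str  # "ok" or "skipped"
    pixels: np.ndarray | None = None
    visible: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def sample_fiducials_with_pointer(
    truth, noise_mm: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pointer-tip samples of the phantom fiducials, in the patient-reference
    frame, with seeded isotropic Gaussian tip-localization noise.

    ``truth`` is a :class:`~endonav.phantom_sim.PhantomModel`. Returns
    ``(ids, points)``.
    """
    if noise_mm < 0:
        raise ValueError("noise_mm must be >= 0")
    from .phantom_sim import derive_rng  # local: phantom_sim imports this module

    pts_ref = truth.patientref_from_ct.apply(truth.fiducials.points_ct)
    if noise_mm > 0:
        rng = derive_rng(seed, "pointer")
        pts_ref = pts_ref + rng.normal(scale=noise_mm, size=pts_ref.shape)
    return truth.fiducials.ids.copy(), pts_ref


def register_ir(
    fiducials_ct: FiducialSet,
    sampled_ids: np.ndarray,
    sampled_points_ref: np.ndarray,
) -> tuple[RigidTransform, float]:
    """Point-based registration of the CT fiducials to the pointer samples.

    Pairs by fiducial id (proceeding with a warning if some ids are missing,
    as long as >= 3 remain) and delegates to the closed-form Procrustes
    solver. Returns (patientref_from_ct, FRE mm).
    """
    sampled_ids = np.asarray(sampled_ids, dtype=int)
    sampled_points_ref = np.atleast_2d(np.asarray(sampled_points_ref, dtype=float))
    lookup = {int(i): k for k, i in enumerate(sampled_ids)}
    src, dst = [], []
    for k, fid in enumerate(fiducials_ct.ids):
        j = lookup.get(int(fid))
        if j is not None:
            src.append(fiducials_ct.points_ct[k])
            dst.append(sampled_points_ref[j])
    if len(src) < 3:
        raise InsufficientDataError(
            f"only {len(src)} common fiducial ids; need >= 3"
        )
    if len(src) < len(fiducials_ct):
        log.warning(
            "registering with %d of %d fiducials (missing ids dropped)",
            len(src), len(fiducials_ct),
        )
    return procrustes_register(np.asarray(src), np.asarray(dst))


def ir_overlay_chain(
    frame: TrackerFrame,
    endocam_from_endoref: RigidTransform,
    patientref_from_ct: RigidTransform,
    intrinsics: CameraIntrinsics,
    targets_ct: np.ndarray,
) -> OverlayResult:
    """Project CT targets into the endoscope image via the IR chain:
    ``endocam <- endoref <- tracker <- patientref <- ct``.

    A frame in which either body is invalid is skipped with explicit status.
    """
    if not (frame.patientref_valid and frame.endoref_valid):
        return OverlayResult(status="skipped")
    chain = (
        endocam_from_endoref
        .compose(frame.tracker_from_endoref.invert())
        .compose(frame.tracker_from_patientref)
        .compose(patientref_from_ct)
    )
    uv, visible = project(intrinsics, chain, targets_ct)
    return OverlayResult(status="ok", pixels=uv, visible=visible)


# ---------------------------------------------------------------------------
# Tracker log serialization
# ---------------------------------------------------------------------------

_BODY_NAMES = ("patientref", "endoref")


def save_tracker_log_csv(frames: list[TrackerFrame], path) -> None:
    rows = []
    for fr in frames:
        for body, t in (
            ("patientref", fr.tracker_from_patientref),
            ("endoref", fr.tracker_from_endoref),
        ):
            row = {"frame": fr.frame, "body": body, "valid": int(t is not None)}
            m = t.matrix() if t is not None else np.full((4, 4), np.nan)
            for i in range(3):
                for j in range(4):
                    row[f"m{i}{j}"] = m[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_tracker_log_csv(path) -> list[TrackerFrame]:
    df = pd.read_csv(path)
    frames = []
    for frame, g in df.groupby("frame", sort=True):
        bodies: dict[str, RigidTransform | None] = {b: None for b in _BODY_NAMES}
        for _, row in g.iterrows():
            if not int(row["valid"]):
                continue
            m = np.eye(4)
            for i in range(3):
                for j in range(4):
                    m[i, j] = row[f"m{i}{j}"]
            bodies[row["body"]] = RigidTransform.from_matrix(m)
        frames.append(
            TrackerFrame(
                frame=int(frame),
                tracker_from_patientref=bodies["patientref"],
                tracker_from_endoref=bodies["endoref"],
            )
        )
    return frames
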