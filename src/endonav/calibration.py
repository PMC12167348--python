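"""Extrinsic calibration between two rigidly mounted cameras from frames in
which both observed the same board.

Each paired frame yields a closed-form estimate
``E_i = endoscope_from_board_i o inv(trackingcam_from_board_i)``;
the estimates are fused by a chordal rotation mean (orthogonal projection of
the arithmetic mean of the rotation matrices) and an arithmetic translation
mean. Per-frame residuals are reported against the fused estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError
from .geometry3d import (
    RigidTransform,
    orthonormalize_rotation,
    pose_error,
    transform_from_dict,
    transform_to_dict,
)

__all__ = [
    "PairedPoseSet",
    "extrinsic_from_paired_poses",
    "chordal_mean_rotation",
    "average_transforms",
    "save_paired_poses_json",
    "load_paired_poses_json",
]


@dataclass(frozen=True)
class PairedPoseSet:
    """Per-frame board poses seen simultaneously from both cameras."""

    frames: tuple[int, ...]
    endoscope_from_board: tuple[RigidTransform, ...]
    trackingcam_from_board: tuple[RigidTransform, ...]

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(int(f) for f in self.frames))
        object.__setattr__(self, "endoscope_from_board", tuple(self.endoscope_from_board))
        object.__setattr__(self, "trackingcam_from_board", tuple(self.trackingcam_from_board))
        n = len(self.frames)
        if n == 0:
            raise InsufficientDataError("paired pose set must contain >= 1 pair")
        if len(self.endoscope_from_board) != n or len(self.trackingcam_from_board) != n:
            raise ValueError("frames and pose lists must have equal length")
        if len(set(self.frames)) != n:
            raise ValueError("frame indices must be unique")

    def __len__(self) -> int:
        return len(self.frames)


def chordal_mean_rotation(rotations) -> np.ndarray:
    """Chordal L2 mean: project the arithmetic mean matrix back onto SO(3)."""
    rotations = list(rotations)
    if not rotations:
        raise InsufficientDataError("cannot average zero rotations")
    return orthonormalize_rotation(np.mean([np.asarray(r) for r in rotations], axis=0))


def average_transforms(transforms) -> RigidTransform:
    """Chordal rotation mean + arithmetic translation mean."""
    transforms = list(transforms)
    if not transforms:
        raise InsufficientDataError("cannot average zero transforms")
    rot = chordal_mean_rotation(t.rotation for t in transforms)
    trans = np.mean([t.translation for t in transforms], axis=0)
    return RigidTransform(rot, trans)


def extrinsic_from_paired_poses(
    pairs: PairedPoseSet,
    reject_outliers: bool = False,
) -> tuple[RigidTransform, list[tuple[float, float]]]:
    """Fused endoscope_from_trackingcam estimate plus per-frame residuals.

    Residuals are ``pose_error(E_i, fused)`` in (degrees, mm), one per input
    frame (also for frames dropped by the optional outlier gate). With
    ``reject_outliers``, frames whose rotational or translational residual
    exceeds 3x the respective median are dropped and the remainder re-averaged
    once (off by default).
    """
    per_frame = [
        e.compose(t.invert())
        for e, t in zip(pairs.endoscope_from_board, pairs.trackingcam_from_board)
    ]
    fused = average_transforms(per_frame)

    if reject_outliers and len(per_frame) >= 3:
        res = np.array([pose_error(e, fused) for e in per_frame])
        med = np.median(res, axis=0)
        keep = (res[:, 0] <= 3.0 * max(med[0], 1e-12)) & (
            res[:, 1] <= 3.0 * max(med[1], 1e-12)
        )
        if keep.any() and not keep.all():
            fused = average_transforms(
                [e for e, k in zip(per_frame, keep) if k]
            )

    residuals = [pose_error(e, fused) for e in per_frame]
    return fused, residuals


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_paired_poses_json(pairs: PairedPoseSet, path) -> None:
    payload = [
        {
            "frame": f,
            "T_endo_board": transform_to_dict(e),
            "T_track_board": transform_to_dict(t),
        }
        for f, e, t in zip(
            pairs.frames, pairs.endoscope_from_board, pairs.trackingcam_from_board
        )
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_paired_poses_json(path) -> PairedPoseSet:
    payload = json.loads(Path(path).read_text())
    return PairedPoseSet(
        frames=tuple(p["frame"] for p in payload),
        endoscope_from_board=tuple(
            transform_from_dict(p["T_endo_board"]) for p in payload
        ),
        trackingcam_from_board=tuple(
            transform_from_dict(p["T_track_board"]) for p in payload
        ),
    )
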