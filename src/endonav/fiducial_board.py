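"""Planar marker-board geometry and pose estimation from (possibly partial)
detections.

A board is reduced to its grid of interior corner points with stable integer
ids; marker decoding happens upstream (or, here, in simulation), so only the
planar geometry matters. Pose estimation tolerates occlusion: any subset of at
least ``min_points`` non-collinear surviving points is enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camera import CameraIntrinsics, estimate_planar_pose
from .errors import DegenerateGeometryError, InsufficientMarkersError
from .geometry3d import RigidTransform

__all__ = [
    "MarkerBoard",
    "BoardDetection",
    "make_board",
    "board_pose_from_detection",
    "save_board_yaml",
    "load_board_yaml",
    "save_detections_csv",
    "load_detections_csv",
]


@dataclass(frozen=True)
class MarkerBoard:
    """Planar grid of identified points on the z=0 board plane (mm)."""

    board_id: str
    point_ids: np.ndarray  # (P,) int
    points_mm: np.ndarray  # (P, 2) in-plane coordinates
    square_mm: float
    rows: int
    cols: int

    def __post_init__(self):
        ids = np.array(self.point_ids, dtype=int)
        pts = np.array(self.points_mm, dtype=float)
        if ids.shape[0] != pts.shape[0] or pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("point_ids (P,) and points_mm (P,2) must match")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("board point ids must be unique")
        ids.setflags(write=False)
        pts.setflags(write=False)
        object.__setattr__(self, "point_ids", ids)
        object.__setattr__(self, "points_mm", pts)

    def __len__(self) -> int:
        return len(self.point_ids)

    @property
    def points_3d(self) -> np.ndarray:
        """(P, 3) board-frame coordinates with z = 0."""
        return np.column_stack([self.points_mm, np.zeros(len(self))])

    def match_detection(self, det: "BoardDetection") -> tuple[np.ndarray, np.ndarray]:
        """Return (board_xy_mm, pixels) for the detected ids, detection order."""
        index = {int(i): k for k, i in enumerate(self.point_ids)}
        try:
            rows = [index[int(i)] for i in det.point_ids]
        except KeyError as e:
            raise ValueError(f"detection references unknown point id {e}") from None
        return self.points_mm[rows], np.array(det.pixels, dtype=float)


@dataclass(frozen=True)
class BoardDetection:
    """Noisy 2-D observations of a subset of board points in one frame."""

    frame: int
    camera_id: str
    point_ids: np.ndarray  # (D,) int
    pixels: np.ndarray  # (D, 2) px

    def __post_init__(self):
        ids = np.array(self.point_ids, dtype=int)
        px = np.array(self.pixels, dtype=float).reshape(-1, 2)
        if ids.shape[0] != px.shape[0]:
            raise ValueError("point_ids and pixels must have equal length")
        if px.size and not np.all(np.isfinite(px)):
            raise ValueError("pixel coordinates must be finite")
        ids.setflags(write=False)
        px.setflags(write=False)
        object.__setattr__(self, "point_ids", ids)
        object.__setattr__(self, "pixels", px)

    def __len__(self) -> int:
        return len(self.point_ids)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


def make_board(rows: int, cols: int, square_mm: float, board_id: str = "board") -> MarkerBoard:
    """Interior-corner grid of a rows x cols chessboard with the given pitch.

    A rows x cols board of squares has (rows-1) x (cols-1) interior corners;
    the origin is the board corner and the grid lies in the z=0 plane.
    """
    if rows < 2 or cols < 2:
        raise ValueError("board needs rows >= 2 and cols >= 2")
    if square_mm <= 0:
        raise ValueError("square size must be positive")
    xs, ys = np.meshgrid(np.arange(cols - 1), np.arange(rows - 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * square_mm
    return MarkerBoard(
        board_id=board_id,
        point_ids=np.arange(len(pts)),
        points_mm=pts,
        square_mm=float(square_mm),
        rows=rows,
        cols=cols,
    )


def board_pose_from_detection(
    intr: CameraIntrinsics,
    board: MarkerBoard,
    det: BoardDetection,
    min_points: int = 4,
) -> tuple[RigidTransform, int]:
    """Board pose (camera_from_board) from whatever subset of points survived.

    Raises :class:`InsufficientMarkersError` when fewer than ``min_points``
    points were detected — a distinct failure from
    :class:`DegenerateGeometryError` (enough points, but collinear).
    """
    if min_points < 4:
        raise ValueError("min_points must be >= 4 for a planar pose")
    if len(det) < min_points:
        raise InsufficientMarkersError(
            f"insufficient markers: {len(det)} detected, need >= {min_points}"
        )
    obj, uv = board.match_detection(det)
    pose, _rms = estimate_planar_pose(intr, obj, uv)
    return pose, len(det)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_board_yaml(board: MarkerBoard, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "board_id": board.board_id,
                "rows": board.rows,
                "cols": board.cols,
                "square_mm": board.square_mm,
            },
            sort_keys=False,
        )
    )


def load_board_yaml(path) -> MarkerBoard:
    d = yaml.safe_load(Path(path).read_text())
    return make_board(d["rows"], d["cols"], d["square_mm"], d.get("board_id", "board"))


def save_detections_csv(detections: list[BoardDetection], path) -> None:
    rows = []
    for det in detections:
        for pid, (u, v) in zip(det.point_ids, det.pixels):
            rows.append(
                {"frame": det.frame, "camera": det.camera_id,
                 "point_id": int(pid), "u_px": u, "v_px": v}
            )
    pd.DataFrame(rows, columns=["frame", "camera", "point_id", "u_px", "v_px"]).to_csv(
        path, index=False
    )


def load_detections_csv(path) -> list[BoardDetection]:
    df = pd.read_csv(path)
    out = []
    for (frame, cam), g in df.groupby(["frame", "camera"], sort=True):
        out.append(
            BoardDetection(
                frame=int(frame),
                camera_id=str(cam),
                point_ids=g["point_id"].to_numpy(),
                pixels=g[["u_px", "v_px"]].to_numpy(),
            )
        )
    return out
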