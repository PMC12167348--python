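"""Overlay transform chain, projected target-registration-error metric, and
the seeded two-system comparison experiment.

Projected TRE: for each target, the true pixel (truth chain) and the overlay
pixel (estimated chain) are back-projected onto the plane perpendicular to
the optical axis at the target's *true* camera-frame depth; the error is the
Euclidean distance in that plane (mm), which reduces to ``z * dpx / f`` for a
pure pixel offset. Raw pixel distances are reported alongside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import PairedPoseSet, extrinsic_from_paired_poses
from .camera import (
    CameraIntrinsics,
    _pixels_to_normalized,
    backproject_depth,
    intrinsics_from_dict,
    intrinsics_to_dict,
    project,
)
from .errors import EndonavError, NoVisibleTargetsError
from .fiducial_board import BoardDetection, MarkerBoard, board_pose_from_detection, make_board
from .geometry3d import RigidTransform, look_at, random_pose, transform_from_dict, transform_to_dict
from .ir_baseline import OverlayResult, ir_overlay_chain, register_ir, sample_fiducials_with_pointer
from .phantom_sim import (
    NoiseConfig,
    PhantomModel,
    PhantomParams,
    derive_rng,
    make_phantom,
    observe_board,
    observe_tracker,
    render_depth,
    simulated_ct_surface,
)
from .registration import (
    ICPConfig,
    PointCloud,
    compose_ct_to_reference,
    icp_point_to_plane_robust,
    initial_align_from_prior,
)

__all__ = [
    "TREReport",
    "our_overlay_chain",
    "our_chain_transform",
    "projected_tre",
    "ExperimentConfig",
    "ComparisonResult",
    "run_comparison_experiment",
    "track_sequence",
    "plot_overlay_comparison",
]


@dataclass(frozen=True)
class TREReport:
    """Per-target projected errors plus aggregates for one system/frame."""

    errors_mm: np.ndarray
    system: str = ""
    pixel_errors_px: np.ndarray | None = None
    mean_mm: float = field(init=False)
    std_mm: float = field(init=False)
    n_targets: int = field(init=False)

    def __post_init__(self):
        e = np.array(self.errors_mm, dtype=float).reshape(-1)
        if e.size == 0:
            raise NoVisibleTargetsError("TRE report needs >= 1 target")
        if np.any(e < 0) or not np.all(np.isfinite(e)):
            raise ValueError("errors must be finite and >= 0")
        e.setflags(write=False)
        object.__setattr__(self, "errors_mm", e)
        if self.pixel_errors_px is not None:
            p = np.array(self.pixel_errors_px, dtype=float).reshape(-1)
            p.setflags(write=False)
            object.__setattr__(self, "pixel_errors_px", p)
        object.__setattr__(self, "mean_mm", float(np.mean(e)))
        object.__setattr__(self, "std_mm", float(np.std(e, ddof=1)) if e.size > 1 else 0.0)
        object.__setattr__(self, "n_targets", int(e.size))


def our_chain_transform(
    trackcam_from_board_t: RigidTransform,
    endo_from_trackcam: RigidTransform,
    board_from_ct: RigidTransform,
) -> RigidTransform:
    """endocam <- trackcam <- board <- ct."""
    return endo_from_trackcam.compose(trackcam_from_board_t).compose(board_from_ct)


def our_overlay_chain(
    trackcam_from_board_t: RigidTransform,
    endo_from_trackcam: RigidTransform,
    board_from_ct: RigidTransform,
    intrinsics: CameraIntrinsics,
    targets_ct: np.ndarray,
) -> OverlayResult:
    """Project CT targets into the endoscope image via the on-board chain."""
    chain = our_chain_transform(trackcam_from_board_t, endo_from_trackcam, board_from_ct)
    uv, visible = project(intrinsics, chain, targets_ct)
    return OverlayResult(status="ok", pixels=uv, visible=visible)


def track_sequence(
    intrinsics: CameraIntrinsics,
    board: MarkerBoard,
    detections: list[BoardDetection],
    min_points: int = 4,
) -> list[tuple[RigidTransform | None, bool]]:
    """Per-frame board poses with the hold-last-pose overlay policy.

    Frames whose detection cannot produce a pose reuse the previous pose and
    are flagged ``held=True``; leading frames with no pose yet yield (None,
    True).
    """
    out: list[tuple[RigidTransform | None, bool]] = []
    last: RigidTransform | None = None
    for det in detections:
        try:
            pose, _ = board_pose_from_detection(intrinsics, board, det, min_points)
            last = pose
            out.append((pose, False))
        except EndonavError:
            out.append((last, True))
    return out


def projected_tre(
    true_targets_ct: np.ndarray,
    truth_chain: RigidTransform,
    estimated_chain: RigidTransform,
    intrinsics: CameraIntrinsics,
    system: str = "",
) -> TREReport:
    """Projected TRE between the truth and estimate chains over the targets.

    Both chains map CT coordinates to the endoscope camera frame. Targets must
    be visible through both chains; the metric-plane conversion uses the true
    camera-frame depth of each target.
    """
    targets = np.atleast_2d(np.asarray(true_targets_ct, dtype=float))
    uv_t, vis_t = project(intrinsics, truth_chain, targets)
    uv_e, vis_e = project(intrinsics, estimated_chain, targets)
    mutual = vis_t & vis_e
    if not mutual.any():
        raise NoVisibleTargetsError("no target visible through both chains")
    z = truth_chain.apply(targets)[mutual, 2]
    xy_t = _pixels_to_normalized(intrinsics, uv_t[mutual])
    xy_e = _pixels_to_normalized(intrinsics, uv_e[mutual])
    errors = z * np.linalg.norm(xy_t - xy_e, axis=1)
    pixel_errors = np.linalg.norm(uv_t[mutual] - uv_e[mutual], axis=1)
    return TREReport(errors_mm=errors, system=system, pixel_errors_px=pixel_errors)


# ---------------------------------------------------------------------------
# Comparison experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the end-to-end two-system simulation needs."""

    phantom: PhantomParams = PhantomParams()
    noise: NoiseConfig = NoiseConfig()
    icp: ICPConfig = ICPConfig()
    # cameras
    endoscope_intrinsics: CameraIntrinsics = CameraIntrinsics(
        fx=1000.0, fy=1000.0, cx=960.0, cy=540.0, width=1920, height=1080
    )
    # tracking camera: full-resolution color stream (board detection) and a
    # decimated depth stream (reconstruction), like the physical sensor
    trackcam_intrinsics: CameraIntrinsics = CameraIntrinsics(
        fx=680.0, fy=680.0, cx=640.0, cy=360.0, width=1280, height=720
    )
    trackcam_depth_intrinsics: CameraIntrinsics = CameraIntrinsics(
        fx=110.0, fy=110.0, cx=80.0, cy=60.0, width=160, height=120
    )
    # boards
    tracking_board_rows: int = 4
    tracking_board_cols: int = 6
    tracking_board_square_mm: float = 30.0
    calib_board_rows: int = 5
    calib_board_cols: int = 9
    calib_board_square_mm: float = 20.0
    ct_from_calibboard: RigidTransform = RigidTransform.from_rotvec_deg(
        (5.0, 0.0, 0.0), (20.0, -80.0, 0.0)
    )
    # rig geometry (true transforms the calibration must recover)
    endo_from_trackcam: RigidTransform = RigidTransform.from_rotvec_deg(
        (2.3, 7.4, 1.5), (35.0, 10.0, -25.0)
    )
    endocam_from_endoref: RigidTransform = RigidTransform.from_rotvec_deg(
        (4.0, -2.0, 1.0), (20.0, -30.0, 50.0)
    )
    rig_eye_offset: tuple[float, float, float] = (10.0, -20.0, 290.0)
    tracker_eye: tuple[float, float, float] = (150.0, -1900.0, 700.0)
    # protocol
    n_calibration_frames: int = 20
    calib_rot_jitter_deg: float = 10.0
    calib_trans_jitter_mm: float = 40.0
    eval_rot_jitter_deg: float = 5.0
    eval_trans_jitter_mm: float = 15.0
    max_icp_points: int = 1500
    ct_resolution_scale: float = 1.0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "noise": self.noise.to_dict(),
            "icp": dataclasses.asdict(self.icp),
            "endoscope_intrinsics": intrinsics_to_dict(self.endoscope_intrinsics),
            "trackcam_intrinsics": intrinsics_to_dict(self.trackcam_intrinsics),
            "trackcam_depth_intrinsics": intrinsics_to_dict(self.trackcam_depth_intrinsics),
            "tracking_board_rows": self.tracking_board_rows,
            "tracking_board_cols": self.tracking_board_cols,
            "tracking_board_square_mm": self.tracking_board_square_mm,
            "calib_board_rows": self.calib_board_rows,
            "calib_board_cols": self.calib_board_cols,
            "calib_board_square_mm": self.calib_board_square_mm,
            "ct_from_calibboard": transform_to_dict(self.ct_from_calibboard),
            "endo_from_trackcam": transform_to_dict(self.endo_from_trackcam),
            "endocam_from_endoref": transform_to_dict(self.endocam_from_endoref),
            "rig_eye_offset": list(self.rig_eye_offset),
            "tracker_eye": list(self.tracker_eye),
            "n_calibration_frames": self.n_calibration_frames,
            "calib_rot_jitter_deg": self.calib_rot_jitter_deg,
            "calib_trans_jitter_mm": self.calib_trans_jitter_mm,
            "eval_rot_jitter_deg": self.eval_rot_jitter_deg,
            "eval_trans_jitter_mm": self.eval_trans_jitter_mm,
            "max_icp_points": self.max_icp_points,
            "ct_resolution_scale": self.ct_resolution_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        kwargs = {}
        if "phantom" in d:
            p = dict(d.pop("phantom"))
            for key in ("half_axes", "nose_direction"):
                if key in p:
                    p[key] = tuple(p[key])
            kwargs["phantom"] = PhantomParams(**p)
        if "noise" in d:
            kwargs["noise"] = NoiseConfig.from_dict(d.pop("noise"))
        if "icp" in d:
            kwargs["icp"] = ICPConfig(**d.pop("icp"))
        for key in ("endoscope_intrinsics", "trackcam_intrinsics", "trackcam_depth_intrinsics"):
            if key in d:
                kwargs[key] = intrinsics_from_dict(d.pop(key))
        for key in ("ct_from_calibboard", "endo_from_trackcam", "endocam_from_endoref"):
            if key in d:
                kwargs[key] = transform_from_dict(d.pop(key))
        for key in ("rig_eye_offset", "tracker_eye"):
            if key in d:
                kwargs[key] = tuple(d.pop(key))
        kwargs.update(d)
        return cls(**kwargs)

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived geometry --------------------------------------------------
    def tracking_board(self) -> MarkerBoard:
        return make_board(
            self.tracking_board_rows, self.tracking_board_cols,
            self.tracking_board_square_mm, "tracking",
        )

    def calib_board(self) -> MarkerBoard:
        return make_board(
            self.calib_board_rows, self.calib_board_cols,
            self.calib_board_square_mm, "charuco",
        )


@dataclass
class ComparisonResult:
    config: ExperimentConfig
    seed: int
    ours: list[TREReport | None]
    ir: list[TREReport | None]
    failures: list[tuple[int, str, str]]

    def _means(self, reports) -> np.ndarray:
        return np.array([r.mean_mm for r in reports if r is not None])

    def summary(self) -> dict:
        out = {}
        for name, reports in (("ours", self.ours), ("ir", self.ir)):
            m = self._means(reports)
            out[name] = {
                "mean_tre_mm": float(m.mean()) if m.size else None,
                "std_tre_mm": float(m.std(ddof=1)) if m.size > 1 else 0.0,
                "n_repetitions": int(m.size),
            }
        mo, mi = out["ours"]["mean_tre_mm"], out["ir"]["mean_tre_mm"]
        out["ours_better"] = bool(mo is not None and mi is not None and mo < mi)
        out["n_failures"] = len(self.failures)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, reports in (("ours", self.ours), ("ir", self.ir)):
            for rep, r in enumerate(reports):
                if r is None:
                    continue
                rows.append(
                    {
                        "repetition": rep,
                        "system": name,
                        "mean_tre_mm": r.mean_mm,
                        "std_tre_mm": r.std_mm,
                        "n_targets": r.n_targets,
                        "mean_tre_px": float(np.mean(r.pixel_errors_px))
                        if r.pixel_errors_px is not None
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _world_geometry(cfg: ExperimentConfig, phantom: PhantomModel):
    """Nominal (registration-frame) rig pose and static scene transforms."""
    face_center_ct = np.array([0.0, 0.0, phantom.params.half_axes[2] * 0.55])
    board = cfg.tracking_board()
    board_center_board = np.append(board.points_mm.mean(axis=0), 0.0)
    world_from_board = phantom.world_from_ct.compose(phantom.board_from_ct.invert())
    aim = 0.5 * (
        phantom.world_from_ct.apply(face_center_ct)
        + world_from_board.apply(board_center_board)
    )
    eye = aim + np.asarray(cfg.rig_eye_offset, dtype=float)
    trackcam_from_world = look_at(eye, aim)
    world_from_calibboard = phantom.world_from_ct.compose(cfg.ct_from_calibboard)
    world_from_tracker = look_at(np.asarray(cfg.tracker_eye), aim).invert()
    return {
        "trackcam_from_world": trackcam_from_world,
        "world_from_board": world_from_board,
        "world_from_calibboard": world_from_calibboard,
        "world_from_tracker": world_from_tracker,
    }


def _simulate_our_system(
    cfg: ExperimentConfig,
    phantom: PhantomModel,
    geo: dict,
    eval_rig: RigidTransform,  # trackcam_from_world at the evaluation frame
    rep_seed: int,
) -> RigidTransform:
    """Run calibration -> registration -> tracking; return the estimated
    endocam_from_ct chain at the evaluation frame."""
    noise = cfg.noise
    board = cfg.tracking_board()
    calib_board = cfg.calib_board()
    endo_intr, track_intr = cfg.endoscope_intrinsics, cfg.trackcam_intrinsics
    nominal = geo["trackcam_from_world"]

    # --- extrinsic calibration from paired board poses
    frames, endo_poses, track_poses = [], [], []
    for i in range(cfg.n_calibration_frames):
        rig_i = random_pose(
            derive_rng(rep_seed, "calib-rig", str(i)),
            cfg.calib_rot_jitter_deg, cfg.calib_trans_jitter_mm,
        ).compose(nominal)
        endo_i = cfg.endo_from_trackcam.compose(rig_i)
        det_t = observe_board(
            calib_board, geo["world_from_calibboard"], rig_i, track_intr,
            noise, seed=rep_seed, frame=i, camera_id="trackcam",
        )
        det_e = observe_board(
            calib_board, geo["world_from_calibboard"], endo_i, endo_intr,
            noise, seed=rep_seed, frame=i, camera_id="endo",
        )
        try:
            p_t, _ = board_pose_from_detection(track_intr, calib_board, det_t)
            p_e, _ = board_pose_from_detection(endo_intr, calib_board, det_e)
        except EndonavError:
            continue
        frames.append(i)
        endo_poses.append(p_e)
        track_poses.append(p_t)
    pairs = PairedPoseSet(tuple(frames), tuple(endo_poses), tuple(track_poses))
    endo_from_trackcam_est, _ = extrinsic_from_paired_poses(pairs)

    # --- registration at the nominal rig pose
    dm = render_depth(phantom, nominal, cfg.trackcam_depth_intrinsics, noise, seed=rep_seed)
    cloud = backproject_depth(dm)
    if len(cloud) > cfg.max_icp_points:
        sel = derive_rng(rep_seed, "subsample").choice(
            len(cloud), size=cfg.max_icp_points, replace=False
        )
        cloud = PointCloud(cloud.points[sel])
    trackcam_from_ct_true = nominal.compose(phantom.world_from_ct)
    prior = random_pose(
        derive_rng(rep_seed, "prior"), noise.prior_rot_deg, noise.prior_trans_mm
    ).compose(trackcam_from_ct_true)
    ct_mesh = simulated_ct_surface(
        phantom, noise.ct_jitter_mm, cfg.ct_resolution_scale, seed=rep_seed
    )
    target = initial_align_from_prior(ct_mesh, prior)
    result = icp_point_to_plane_robust(cloud, target, cfg.icp)
    trackcam_from_ct_est = result.transform.invert().compose(prior)

    det_reg = observe_board(
        board, geo["world_from_board"], nominal, track_intr,
        noise, seed=rep_seed, frame=10_000, camera_id="trackcam",
    )
    trackcam_from_board_reg, _ = board_pose_from_detection(track_intr, board, det_reg)
    board_from_ct_est = compose_ct_to_reference(
        trackcam_from_ct_est, trackcam_from_board_reg
    )

    # --- tracking at the evaluation frame
    det_eval = observe_board(
        board, geo["world_from_board"], eval_rig, track_intr,
        noise, seed=rep_seed, frame=20_000, camera_id="trackcam",
    )
    trackcam_from_board_t, _ = board_pose_from_detection(track_intr, board, det_eval)
    return our_chain_transform(
        trackcam_from_board_t, endo_from_trackcam_est, board_from_ct_est
    )


def _simulate_ir_system(
    cfg: ExperimentConfig,
    phantom: PhantomModel,
    geo: dict,
    eval_rig: RigidTransform,
    rep_seed: int,
) -> RigidTransform:
    """IR comparator: pointer registration + dual-reference tracking chain."""
    noise = cfg.noise
    ids, samples = sample_fiducials_with_pointer(phantom, noise.pointer_mm, rep_seed)
    patientref_from_ct_est, _fre = register_ir(phantom.fiducials, ids, samples)

    handeye_err = random_pose(
        derive_rng(rep_seed, "handeye"), noise.handeye_rot_deg, noise.handeye_trans_mm
    )
    endocam_from_endoref_est = handeye_err.compose(cfg.endocam_from_endoref)

    endocam_from_world = cfg.endo_from_trackcam.compose(eval_rig)
    world_from_endoref = endocam_from_world.invert().compose(cfg.endocam_from_endoref)
    frame = observe_tracker(
        phantom, world_from_endoref, geo["world_from_tracker"],
        noise, frame=20_000, seed=rep_seed,
    )
    return (
        endocam_from_endoref_est
        .compose(frame.tracker_from_endoref.invert())
        .compose(frame.tracker_from_patientref)
        .compose(patientref_from_ct_est)
    )


def run_comparison_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    n_repetitions: int = 100,
    seed: int = 0,
) -> ComparisonResult:
    """Simulate both systems end-to-end on the same phantom, per repetition.

    Each repetition draws fresh sensor noise (child-seeded from ``seed``) and
    evaluates both systems at the same static endoscope viewpoint. Stage
    failures are recorded per repetition and do not abort the batch.
    """
    phantom = make_phantom(config.phantom)
    geo = _world_geometry(config, phantom)
    ours: list[TREReport | None] = []
    ir: list[TREReport | None] = []
    failures: list[tuple[int, str, str]] = []

    for rep in range(n_repetitions):
        rep_seed = int(derive_rng(seed, "rep", str(rep)).integers(2**31))
        eval_rig = random_pose(
            derive_rng(rep_seed, "eval-rig"),
            config.eval_rot_jitter_deg, config.eval_trans_jitter_mm,
        ).compose(geo["trackcam_from_world"])
        endocam_from_world = config.endo_from_trackcam.compose(eval_rig)
        truth_chain = endocam_from_world.compose(phantom.world_from_ct)

        for name, sim in (("ours", _simulate_our_system), ("ir", _simulate_ir_system)):
            store = ours if name == "ours" else ir
            try:
                est_chain = sim(config, phantom, geo, eval_rig, rep_seed)
                store.append(
                    projected_tre(
                        phantom.targets_ct, truth_chain, est_chain,
                        config.endoscope_intrinsics, system=name,
                    )
                )
            except EndonavError as e:
                store.append(None)
                failures.append((rep, name, str(e)))

    return ComparisonResult(config=config, seed=seed, ours=ours, ir=ir, failures=failures)


def plot_overlay_comparison(
    phantom: PhantomModel,
    truth_chain: RigidTransform,
    est_chains: dict[str, RigidTransform],
    intrinsics: CameraIntrinsics,
    path,
) -> None:
    """True-vs-overlay dot figure: grey circles = truth, red dots = overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(est_chains), figsize=(5 * len(est_chains), 4.5))
    axes = np.atleast_1d(axes)
    uv_t, vis_t = project(intrinsics, truth_chain, phantom.targets_ct)
    for ax, (name, chain) in zip(axes, est_chains.items()):
        uv_e, vis_e = project(intrinsics, chain, phantom.targets_ct)
        m = vis_t & vis_e
        ax.scatter(uv_t[m, 0], uv_t[m, 1], s=120, facecolors="none",
                   edgecolors="grey", label="true targets")
        ax.scatter(uv_e[m, 0], uv_e[m, 1], s=18, c="red", label="overlay")
        ax.set_title(name)
        ax.set_xlabel("u (px)")
        ax.set_ylabel("v (px)")
        ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
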