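"""Per-frame limb reconstruction: landmarks, joint centers, segment-length
optimization and the 9-DOF joint-angle time series.

The reconstruction chain is sequential: global landmark positions from
sensor poses and calibrated offsets; joint centers (shoulder from the
sphere-fit offset, elbow/wrist as landmark midpoints); reference segment
lengths measured over a sedentary window and then imposed on the chain by a
proximal-to-distal sweep (soft-tissue artifact shows up as time-varying
inter-center distances); anatomical frames from the corrected centers and
landmark axes; and finally intrinsic Z-X-Y Cardan angles per joint, read as
flexion/extension, adduction/abduction, internal/external rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .calibration import LimbModel, SurfacePlane, midpoint_center
from .geometry import apply_pose, orthonormal_frame, rotation_from_quat
from .io import TrialRecording

CHANNELS = (
    "shoulder_flex",
    "shoulder_abd",
    "shoulder_rot",
    "elbow_flex",
    "elbow_abd",
    "elbow_rot",
    "wrist_flex",
    "wrist_abd",
    "wrist_rot",
)

GIMBAL_MARGIN_DEG = 1.0


@dataclass
class ReconstructedTrial:
    """Global-frame positions of every registered point, per frame."""

    fs: float
    t: np.ndarray
    landmarks: dict[str, np.ndarray]  # name -> (n, 3)
    joint_centers: dict[str, np.ndarray]  # shoulder/elbow/wrist -> (n, 3)
    working_point: np.ndarray  # (n, 3)
    surface: SurfacePlane  # world frame (from the core-base pose at frame 0)
    hand_sensor_pos: np.ndarray  # (n, 3)
    reference_lengths: dict[str, float] = field(default_factory=dict)
    length_artifact_sd: dict[str, float] = field(default_factory=dict)


def reconstruct_landmarks(rec: TrialRecording, model: LimbModel) -> ReconstructedTrial:
    """Map every calibrated offset through its sensor's pose stream:
    ``x_global(t) = p_sensor(t) + R(q_sensor(t)) offset``."""
    needed = {r.sensor for r in model.landmark_offsets.values()}
    needed |= {model.working_point_offset.sensor, "scapula", "core_base"}
    missing = sorted(needed - set(rec.tracks))
    if missing:
        raise ValueError(f"recording is missing sensors required by the model: {missing}")

    landmarks = {}
    for name, lrec in model.landmark_offsets.items():
        tr = rec.tracks[lrec.sensor]
        landmarks[name] = apply_pose(tr.pos, tr.quat, lrec.offset)

    sc = rec.tracks["scapula"]
    shoulder = apply_pose(sc.pos, sc.quat, model.shoulder_offset)
    elbow = midpoint_center(landmarks["epicondyle_lat"], landmarks["epicondyle_med"])
    wrist = midpoint_center(landmarks["styloid_lat"], landmarks["styloid_med"])

    hand = rec.tracks[model.working_point_offset.sensor]
    working_point = apply_pose(hand.pos, hand.quat, model.working_point_offset.offset)

    core = rec.tracks["core_base"]
    surf_point = apply_pose(core.pos[0], core.quat[0], model.striking_surface.point)
    surf_normal = rotation_from_quat(core.quat[0]).apply(model.striking_surface.normal)

    return ReconstructedTrial(
        fs=rec.fs,
        t=rec.t.copy(),
        landmarks=landmarks,
        joint_centers={"shoulder": shoulder, "elbow": elbow, "wrist": wrist},
        working_point=working_point,
        surface=SurfacePlane(surf_point, surf_normal),
        hand_sensor_pos=hand.pos.copy(),
    )


# ---------------------------------------------------------------------------
# segment lengths
# ---------------------------------------------------------------------------

_SEGMENTS = (("upper_arm", "shoulder", "elbow"), ("forearm", "elbow", "wrist"))


def measure_segment_lengths(
    centers: dict[str, np.ndarray],
    sedentary_window: tuple[int, int],
) -> tuple[dict[str, float], dict[str, float]]:
    """Reference segment lengths from a sedentary period.

    Returns ``(mean_lengths, sd)`` over the window frames; the SD is the
    apparent soft-tissue artifact magnitude. The window must hold at least
    10 frames and lie inside the recording.
    """
    lo, hi = sedentary_window
    n = len(next(iter(centers.values())))
    if lo < 0 or hi > n or hi - lo < 10:
        raise ValueError(
            f"sedentary window [{lo}, {hi}) must lie inside the recording "
            f"(n={n}) and span at least 10 frames"
        )
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name, prox, dist in _SEGMENTS:
        d = np.linalg.norm(centers[dist][lo:hi] - centers[prox][lo:hi], axis=1)
        means[name] = float(d.mean())
        sds[name] = float(d.std())
    return means, sds


def enforce_segment_lengths(
    centers: dict[str, np.ndarray], reference_lengths: dict[str, float]
) -> dict[str, np.ndarray]:
    """Impose the recalculated segment lengths on the chain.

    Proximal-to-distal sweep: each distal center is re-placed on the ray
    from its (already corrected) proximal center through the raw distal
    center, at exactly the reference length. Idempotent; inter-center
    distances are exactly constant afterwards.
    """
    for name, length in reference_lengths.items():
        if not length > 0:
            raise ValueError(f"reference length '{name}' must be > 0")
    corrected = {"shoulder": centers["shoulder"].copy()}
    prox_corr = corrected["shoulder"]
    for name, prox, dist in _SEGMENTS:
        ray = centers[dist] - prox_corr
        norms = np.linalg.norm(ray, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise ValueError(
                f"coincident {prox}/{dist} centers: zero-length ray, cannot "
                "impose segment length"
            )
        corrected[dist] = prox_corr + reference_lengths[name] * ray / norms
        prox_corr = corrected[dist]
    return corrected


def apply_length_correction(
    recon: ReconstructedTrial, sedentary_window: tuple[int, int]
) -> ReconstructedTrial:
    """Measure reference lengths over the sedentary window and enforce them."""
    lengths, sds = measure_segment_lengths(recon.joint_centers, sedentary_window)
    recon.joint_centers = enforce_segment_lengths(recon.joint_centers, lengths)
    recon.reference_lengths = lengths
    recon.length_artifact_sd = sds
    return recon


# ---------------------------------------------------------------------------
# anatomical frames and joint angles
# ---------------------------------------------------------------------------


def _torso_frames(landmarks: dict[str, np.ndarray]) -> np.ndarray:
    """Torso frame rule: z along c7 -> acromion (mediolateral proxy),
    x-hint from c7 -> suprasternale, y completing the right-handed triad."""
    z = landmarks["acromion"] - landmarks["c7"]
    x_raw = landmarks["suprasternale"] - landmarks["c7"]
    y = np.cross(z, x_raw)
    return orthonormal_frame(y, z)


def anatomical_frames(
    landmarks: dict[str, np.ndarray], centers: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Segment frames (n, 3, 3; columns x anterior, y proximal, z mediolateral)
    built from corrected joint centers and bony-landmark axes."""
    return {
        "torso": _torso_frames(landmarks),
        "upper_arm": orthonormal_frame(
            centers["shoulder"] - centers["elbow"],
            landmarks["epicondyle_lat"] - landmarks["epicondyle_med"],
        ),
        "forearm": orthonormal_frame(
            centers["elbow"] - centers["wrist"],
            landmarks["styloid_lat"] - landmarks["styloid_med"],
        ),
        "hand": orthonormal_frame(
            centers["wrist"]
            - 0.5 * (landmarks["mc2_head"] + landmarks["mc5_head"]),
            landmarks["mc2_head"] - landmarks["mc5_head"],
        ),
    }


@dataclass
class JointAngleSeries:
    """The nine joint-angle channels in degrees, unwrapped for continuity."""

    fs: float
    t: np.ndarray
    angles_deg: np.ndarray  # (n, 9), CHANNELS order
    gimbal_flags: np.ndarray  # (n,) bool: any joint near the +-90 deg singularity
    channel_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.channel_means = self.angles_deg.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles_deg, columns=list(CHANNELS))
        df.insert(0, "t", self.t)
        df["gimbal_flag"] = self.gimbal_flags
        return df


def compute_joint_angles(recon: ReconstructedTrial) -> JointAngleSeries:
    """Intrinsic Z-X-Y Cardan decomposition of each distal anatomical frame
    in its proximal frame (flex/ext, add/abd, int/ext rotation, degrees).

    Channels are unwrapped to avoid 360-degree jumps; frames where any
    second (add/abd) angle comes within 1 degree of +-90 are flagged as
    gimbal-adjacent rather than rejected.
    """
    frames = anatomical_frames(recon.landmarks, recon.joint_centers)
    n = len(recon.t)
    angles = np.empty((n, 9))
    for j, (prox, dist) in enumerate(
        (("torso", "upper_arm"), ("upper_arm", "forearm"), ("forearm", "hand"))
    ):
        rel = np.matmul(np.swapaxes(frames[prox], -1, -2), frames[dist])
        eul = Rotation.from_matrix(rel).as_euler("ZXY", degrees=True)
        angles[:, 3 * j : 3 * j + 3] = np.atleast_2d(eul)
    angles = np.rad2deg(np.unwrap(np.deg2rad(angles), axis=0))
    gimbal = np.zeros(n, dtype=bool)
    for j in range(3):
        gimbal |= np.abs(np.abs(angles[:, 3 * j + 1]) - 90.0) < GIMBAL_MARGIN_DEG
    return JointAngleSeries(fs=recon.fs, t=recon.t.copy(), angles_deg=angles, gimbal_flags=gimbal)


def reconstruct_trial(
    rec: TrialRecording,
    model: LimbModel,
    sedentary_window_s: tuple[float, float] = (0.0, 2.0),
    enforce_lengths: bool = True,
) -> tuple[ReconstructedTrial, JointAngleSeries]:
    """Full per-trial reconstruction: landmarks, centers, optional length
    enforcement over the sedentary window, and joint angles."""
    recon = reconstruct_landmarks(rec, model)
    if enforce_lengths:
        lo = int(round(sedentary_window_s[0] * rec.fs))
        hi = int(round(sedentary_window_s[1] * rec.fs))
        recon = apply_length_correction(recon, (lo, hi))
    return recon, compute_joint_angles(recon)
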