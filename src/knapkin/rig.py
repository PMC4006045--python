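"""Synthetic forward-kinematics rig for percussive upper-limb trials.

The study this package supports analyzed electromagnetic 6-DOF sensor
streams of the striking arm during stone knapping. No such raw data is
publicly deposited, so this module generates it: a 9-DOF arm (shoulder,
elbow, wrist; three rotational degrees of freedom each) driven through
minimum-jerk striking movements, with rigidly mounted segment sensors, a
stylus-calibration record, a registered hammer working point and core
striking surface, and per-strike flake-mass outcomes. Every quantity the
analysis pipeline later estimates is retained as ground truth, so each
downstream stage has an exact recovery oracle.

Kinematic chain and conventions
-------------------------------
World frame: right-handed, meters, vertical = +Z. Anatomical segment frames
use y along the segment pointing proximally, z mediolateral, x anterior; at
zero joint angles the arm hangs straight down. Each joint rotation is an
intrinsic Z-X-Y Cardan sequence read as flexion/extension, adduction/
abduction, internal/external rotation, in degrees — positive flexion swings
the arm forward and up. The nine channels are ordered::

    shoulder_flex, shoulder_abd, shoulder_rot,
    elbow_flex,    elbow_abd,    elbow_rot,
    wrist_flex,    wrist_abd,    wrist_rot

Strikes are bell-velocity (minimum-jerk) joint-space movements along a
per-strike synergy direction: raise to an apex posture whose working-point
height encodes the target potential energy, then descend to surface contact
with the descent duration chosen so the peak working-point speed encodes the
target kinetic energy. Secondary joint-space components with smaller
variance give each strike a multi-component covariance structure, and
soft-tissue artifact is modeled as low-frequency (0.5-3 Hz) sinusoidal
sensor displacement in the segment frame plus white measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .geometry import (
    QUAT_IDENTITY,
    apply_pose,
    compose_pose,
    invert_pose,
    minimum_jerk,
    quat_from_rotation,
    rotation_from_quat,
)
from .io import (
    CalibrationRecord,
    LandmarkRecord,
    OutcomeRecord,
    SensorTrack,
    TrialRecording,
)

GRAVITY = 9.81  # m/s^2

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

SEGMENT_OF_SENSOR = {
    "scapula": "torso",
    "upper_arm": "upper_arm",
    "forearm": "forearm",
    "hand": "hand",
}

# anatomical-to-world base rotation: anatomical x (anterior) -> world +Y,
# y (superior) -> world +Z, z (mediolateral) -> world +X
R_BASE = Rotation.from_matrix(
    np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
)

_REST_ANGLES = np.array([30.0, 8.0, 0.0, 50.0, 5.0, 0.0, 15.0, 3.0, 0.0])

# flexion-dominated template synergy: raising all three flexion channels
# lifts the hammer; small off-axis weights keep the direction generic
_TEMPLATE_DIRECTION = np.array([0.55, 0.12, 0.06, 0.70, 0.10, 0.08, 0.30, 0.06, 0.05])


@dataclass(frozen=True)
class MountPose:
    """Rigid pose of a sensor in its segment frame (or world, for core_base)."""

    position: np.ndarray
    quat: np.ndarray = field(default_factory=lambda: QUAT_IDENTITY.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "quat", np.asarray(self.quat, dtype=float))
        if abs(np.linalg.norm(self.quat) - 1.0) > 1e-9:
            raise ValueError("sensor mount quaternion must be unit norm")


def _mount(pos: Sequence[float], euler_deg: Sequence[float] = (0, 0, 0)) -> MountPose:
    q = quat_from_rotation(Rotation.from_euler("xyz", euler_deg, degrees=True))
    return MountPose(np.asarray(pos, float), q)


def default_sensor_mounts() -> dict[str, MountPose]:
    """Sensor placements mirroring the experimental layout: dorsal hand,
    dorsal forearm, lateral upper arm, scapula, plus the static core base."""
    return {
        "hand": _mount((0.010, -0.035, 0.015), (4, -6, 12)),
        "forearm": _mount((0.005, -0.120, 0.030), (-7, 12, 30)),
        "upper_arm": _mount((0.010, -0.160, 0.035), (5, 40, 3)),
        "scapula": _mount((-0.020, 0.060, -0.040), (10, 5, -8)),
        "core_base": _mount((0.450, 0.300, 0.280), (0, 0, 25)),
    }


@dataclass
class ArmGroundTruth:
    """Fully specified synthetic arm + task rig with deterministic kinematics."""

    segment_lengths: dict[str, float]  # upper_arm, forearm, hand (m)
    sensor_mounts: dict[str, MountPose]
    hammer_offset: np.ndarray  # working point in HAND-SENSOR frame (m)
    hammer_mass: float = 0.6  # kg
    core_surface_height: float = 0.35  # world z of the striking surface (m)
    shoulder_base: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.95]))
    elbow_width: float = 0.07
    wrist_width: float = 0.05
    hand_width: float = 0.08
    rest_angles_deg: np.ndarray = field(default_factory=lambda: _REST_ANGLES.copy())

    def __post_init__(self) -> None:
        for name in ("upper_arm", "forearm", "hand"):
            if name not in self.segment_lengths:
                raise ValueError(f"segment length '{name}' missing")
            if not self.segment_lengths[name] > 0:
                raise ValueError(f"segment length '{name}' must be > 0")
        for sensor in ("hand", "forearm", "upper_arm", "scapula", "core_base"):
            if sensor not in self.sensor_mounts:
                raise ValueError(f"sensor mount '{sensor}' missing")
        self.hammer_offset = np.asarray(self.hammer_offset, dtype=float)
        self.shoulder_base = np.asarray(self.shoulder_base, dtype=float)
        self.rest_angles_deg = np.asarray(self.rest_angles_deg, dtype=float)

    @property
    def landmarks(self) -> dict[str, tuple[str, np.ndarray]]:
        """Anatomical landmark coordinates, ``name -> (segment, xyz)``.

        Epicondyles straddle the elbow center along the mediolateral axis and
        styloids the wrist center, so their midpoints ARE the joint centers;
        torso landmarks encode the torso frame for the landmark-based frame
        reconstruction rule.
        """
        lua = self.segment_lengths["upper_arm"]
        lfa = self.segment_lengths["forearm"]
        lh = self.segment_lengths["hand"]
        acr = np.array([0.0, 0.03, 0.02])
        return {
            "acromion": ("torso", acr),
            "c7": ("torso", acr - np.array([0.0, 0.0, 0.15])),
            "suprasternale": ("torso", acr + np.array([0.12, 0.0, -0.10])),
            "epicondyle_lat": ("upper_arm", np.array([0.0, -lua, self.elbow_width / 2])),
            "epicondyle_med": ("upper_arm", np.array([0.0, -lua, -self.elbow_width / 2])),
            "styloid_lat": ("forearm", np.array([0.0, -lfa, self.wrist_width / 2])),
            "styloid_med": ("forearm", np.array([0.0, -lfa, -self.wrist_width / 2])),
            "mc2_head": ("hand", np.array([0.0, -lh, self.hand_width / 2])),
            "mc5_head": ("hand", np.array([0.0, -lh, -self.hand_width / 2])),
        }

    @property
    def landmark_sensor(self) -> dict[str, str]:
        seg_to_sensor = {v: k for k, v in SEGMENT_OF_SENSOR.items()}
        return {name: seg_to_sensor[seg] for name, (seg, _) in self.landmarks.items()}

    def working_point_in_hand_segment(self) -> np.ndarray:
        m = self.sensor_mounts["hand"]
        return m.position + rotation_from_quat(m.quat).apply(self.hammer_offset)


def make_arm_model(
    segment_lengths: Sequence[float] | dict[str, float] = (0.30, 0.26, 0.08),
    sensor_mounts: Optional[dict[str, MountPose]] = None,
    hammer_spec: Optional[dict] = None,
    rest_clearance: float = 0.08,
    **kwargs,
) -> ArmGroundTruth:
    """Construct a rig from segment lengths, mounts and a hammer description.

    ``hammer_spec`` takes ``mass`` (kg) and either ``offset`` (working point
    in the hand-sensor frame) or ``working_point_segment`` (in the hand
    segment frame, converted through the hand mount). The rest posture is
    adjusted along the template synergy so the hammer hovers
    ``rest_clearance`` meters above the striking surface between strikes
    (every strike apex then sits above the rest posture, as a knapper holds
    the hammer near the platform between blows).
    """
    if not isinstance(segment_lengths, dict):
        ua, fa, hand = segment_lengths
        segment_lengths = {"upper_arm": float(ua), "forearm": float(fa), "hand": float(hand)}
    mounts = dict(default_sensor_mounts())
    if sensor_mounts:
        mounts.update(sensor_mounts)
    spec = dict(hammer_spec or {})
    mass = float(spec.get("mass", 0.6))
    if mass <= 0:
        raise ValueError("hammer mass must be > 0")
    if "offset" in spec:
        offset = np.asarray(spec["offset"], dtype=float)
    else:
        wp_seg = np.asarray(
            spec.get("working_point_segment", (0.01, -0.18, 0.01)), dtype=float
        )
        m = mounts["hand"]
        offset = rotation_from_quat(m.quat).inv().apply(wp_seg - m.position)
    model = ArmGroundTruth(
        segment_lengths=segment_lengths,
        sensor_mounts=mounts,
        hammer_offset=offset,
        hammer_mass=mass,
        **kwargs,
    )
    if rest_clearance is not None:
        d = _oriented_direction(model, _TEMPLATE_DIRECTION)
        s0 = _solve_posture_scale(
            model, d, model.core_surface_height + rest_clearance, (-120.0, 120.0)
        )
        model.rest_angles_deg = model.rest_angles_deg + s0 * d
    return model


# ---------------------------------------------------------------------------
# joint trajectories
# ---------------------------------------------------------------------------


@dataclass
class JointTrajectory:
    """Time series of the nine joint angles plus optional base translation."""

    fs: float
    angles_deg: np.ndarray  # (n, 9)
    base_translation: Optional[np.ndarray] = None  # (n, 3), added to shoulder_base

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_2d(np.asarray(self.angles_deg, dtype=float))
        if self.angles_deg.shape[1] != 9:
            raise ValueError(
                f"expected 9 joint-angle channels, got {self.angles_deg.shape[1]}"
            )
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("joint-angle curves must be finite")
        if self.base_translation is not None:
            self.base_translation = np.asarray(self.base_translation, dtype=float)
            if self.base_translation.shape != (len(self), 3):
                raise ValueError("base_translation must be (n, 3)")

    def __len__(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


def generate_strike_trajectory(
    amplitudes_per_dof: Sequence[float],
    duration: float,
    fs: float,
    profile: str = "minjerk",
) -> JointTrajectory:
    """Single up-and-back stroke: minimum-jerk rise over the first half and
    mirror-image return over the second, per channel, starting from zero.

    Start and end angular velocities are zero. A trajectory with zero
    amplitude on every channel contains no detectable strike and is rejected.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be > 0")
    if profile != "minjerk":
        raise ValueError(f"unknown profile '{profile}'")
    amp = np.asarray(amplitudes_per_dof, dtype=float)
    if amp.shape != (9,):
        raise ValueError("amplitudes_per_dof must have 9 channels")
    if np.all(amp == 0):
        raise ValueError("degenerate trajectory: zero amplitude on all channels")
    n = int(round(duration * fs))
    tau = np.arange(n) / max(n - 1, 1)
    bell = np.where(tau <= 0.5, minimum_jerk(2 * tau), minimum_jerk(2 * (1 - tau)))
    return JointTrajectory(fs=fs, angles_deg=bell[:, None] * amp[None, :])


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


@dataclass
class RigFrames:
    """Per-frame ground-truth state of the rig (noiseless)."""

    fs: float
    t: np.ndarray
    angles_deg: np.ndarray  # (n, 9)
    joint_centers: dict[str, np.ndarray]  # shoulder/elbow/wrist -> (n, 3)
    landmarks: dict[str, np.ndarray]  # name -> (n, 3)
    sensors: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (pos, quat)
    working_point: np.ndarray  # (n, 3)
    segment_rotations: dict[str, Rotation]

    @property
    def n_frames(self) -> int:
        return len(self.t)


def _joint_rotations(angles_deg: np.ndarray) -> list[Rotation]:
    return [
        Rotation.from_euler("ZXY", angles_deg[:, 3 * j : 3 * j + 3], degrees=True)
        for j in range(3)
    ]


def forward_kinematics(model: ArmGroundTruth, trajectory: JointTrajectory) -> RigFrames:
    """Propagate joint angles through the chain; returns joint centers,
    anatomical landmarks, sensor poses and the hammer working point.

    Rigid-body consistency (constant inter-joint distances) holds to float
    precision because every point is carried by exactly one segment frame.
    """
    ang = trajectory.angles_deg
    n = len(trajectory)
    r_sh, r_el, r_wr = _joint_rotations(ang)
    r_torso = R_BASE
    r_ua = r_torso * r_sh
    r_fa = r_ua * r_el
    r_hand = r_fa * r_wr

    shoulder = np.broadcast_to(model.shoulder_base, (n, 3)).copy()
    if trajectory.base_translation is not None:
        shoulder = shoulder + trajectory.base_translation
    elbow = shoulder + r_ua.apply([0.0, -model.segment_lengths["upper_arm"], 0.0])
    wrist = elbow + r_fa.apply([0.0, -model.segment_lengths["forearm"], 0.0])

    seg_rot: dict[str, Rotation] = {
        "torso": r_torso,
        "upper_arm": r_ua,
        "forearm": r_fa,
        "hand": r_hand,
    }
    seg_origin = {"torso": shoulder, "upper_arm": shoulder, "forearm": elbow, "hand": wrist}

    landmarks = {
        name: seg_origin[seg] + seg_rot[seg].apply(coords)
        for name, (seg, coords) in model.landmarks.items()
    }

    sensors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sensor, segment in SEGMENT_OF_SENSOR.items():
        mount = model.sensor_mounts[sensor]
        rot = seg_rot[segment]
        pos = seg_origin[segment] + rot.apply(mount.position)
        quat = quat_from_rotation(rot * rotation_from_quat(mount.quat))
        if quat.ndim == 1:
            quat = np.broadcast_to(quat, (n, 4)).copy()
        if pos.ndim == 1:
            pos = np.broadcast_to(pos, (n, 3)).copy()
        sensors[sensor] = (pos, quat)
    core = model.sensor_mounts["core_base"]
    sensors["core_base"] = (
        np.broadcast_to(core.position, (n, 3)).copy(),
        np.broadcast_to(core.quat, (n, 4)).copy(),
    )

    hp, hq = sensors["hand"]
    working_point = apply_pose(hp, hq, model.hammer_offset)

    return RigFrames(
        fs=trajectory.fs,
        t=trajectory.t,
        angles_deg=ang,
        joint_centers={"shoulder": shoulder, "elbow": elbow, "wrist": wrist},
        landmarks=landmarks,
        sensors=sensors,
        working_point=working_point,
        segment_rotations=seg_rot,
    )


def render_sensor_tracks(
    frames: RigFrames,
    model: ArmGroundTruth,
    artifact_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    condition: str = "small_600g",
    subject: str = "S0",
    trial: int = 1,
) -> TrialRecording:
    """Turn true poses into a measured recording.

    Soft-tissue artifact: each body sensor is displaced sinusoidally
    (0.5-3 Hz, random phase/axis mix, peak ``artifact_amplitude`` meters) in
    its segment frame, emulating skin/muscle deformation; white Gaussian
    position noise of ``noise_sd`` is added on top. The amplitude is scaled
    per site to the local tissue: full on the muscular upper arm, 0.7 on
    the forearm, 0.25 on the bony hand dorsum and 0.4 on the taped scapula;
    the static core-base sensor gets measurement noise only. The drift is
    anisotropic — dominated by the segment's long axis (skin slides along
    the limb during flexion/extension), with a quarter of the amplitude
    transversely — which is what makes inter-joint distances the visible
    symptom of the artifact.
    """
    if artifact_amplitude < 0:
        raise ValueError("artifact_amplitude must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if (artifact_amplitude > 0 or noise_sd > 0) and rng is None:
        raise ValueError("rng is required when artifact or noise is requested")
    t = frames.t
    tracks: dict[str, SensorTrack] = {}
    for sensor, (pos, quat) in frames.sensors.items():
        pos = pos.copy()
        if artifact_amplitude > 0 and sensor != "core_base":
            site_scale = {"upper_arm": 1.0, "forearm": 0.7, "hand": 0.25, "scapula": 0.4}
            amp = artifact_amplitude * site_scale[sensor]
            seg_rot = frames.segment_rotations[SEGMENT_OF_SENSOR[sensor]]
            drift_local = np.zeros((len(t), 3))
            # axis 1 is the segment's long axis (anatomical y)
            axis_scale = (0.25, 1.0, 0.25)
            for axis in range(3):
                f = rng.uniform(0.5, 3.0)
                phase = rng.uniform(0, 2 * np.pi)
                weight = rng.uniform(0.5, 1.0) * axis_scale[axis]
                drift_local[:, axis] = amp * weight * np.sin(2 * np.pi * f * t + phase)
            pos += seg_rot.apply(drift_local)
        if noise_sd > 0:
            pos += rng.normal(0.0, noise_sd, pos.shape)
        tracks[sensor] = SensorTrack(t=t.copy(), pos=pos, quat=quat.copy())
    return TrialRecording(
        fs=frames.fs,
        tracks=tracks,
        hammer_mass=model.hammer_mass,
        condition=condition,
        subject=subject,
        trial=trial,
    )


def simulate_stylus_calibration(model: ArmGroundTruth) -> CalibrationRecord:
    """Stylus records exactly consistent with the rig.

    Landmark offsets in adjacent-sensor frames are posture independent
    (both live on the same rigid segment), so they are computed directly
    from the mounts. Surface points are four stylus touches on the core
    striking plane, expressed in the core-base sensor frame.
    """
    landmarks: dict[str, LandmarkRecord] = {}
    for name, (segment, coords) in model.landmarks.items():
        sensor = model.landmark_sensor[name]
        mount = model.sensor_mounts[sensor]
        offset = rotation_from_quat(mount.quat).inv().apply(coords - mount.position)
        landmarks[name] = LandmarkRecord(sensor, offset)
    core = model.sensor_mounts["core_base"]
    surface_world = np.array(
        [
            [0.42, 0.28, model.core_surface_height],
            [0.50, 0.29, model.core_surface_height],
            [0.46, 0.35, model.core_surface_height],
            [0.41, 0.33, model.core_surface_height],
        ]
    )
    surface_points = [
        LandmarkRecord("core_base", invert_pose(core.position, core.quat, p))
        for p in surface_world
    ]
    return CalibrationRecord(
        landmarks=landmarks,
        working_point=LandmarkRecord("hand", model.hammer_offset.copy()),
        surface_points=surface_points,
    )


# ---------------------------------------------------------------------------
# strike synthesis
# ---------------------------------------------------------------------------


def _wp_height(model: ArmGroundTruth, angles: np.ndarray) -> float:
    traj = JointTrajectory(fs=1.0, angles_deg=angles[None, :])
    return float(forward_kinematics(model, traj).working_point[0, 2])


def _solve_posture_scale(
    model: ArmGroundTruth,
    direction: np.ndarray,
    target_height: float,
    s_range: tuple[float, float],
) -> float:
    """Scale ``s`` along a joint-space direction so the working-point height
    hits ``target_height``; bisection over a scanned bracket."""
    rest = model.rest_angles_deg

    def height(s: float) -> float:
        return _wp_height(model, rest + s * direction) - target_height

    grid = np.linspace(s_range[0], s_range[1], 120)
    vals = np.array([height(s) for s in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError(
            "strike direction cannot reach the requested working-point height; "
            "increase amplitude range or adjust the rest posture"
        )
    # of all crossings, take the one closest to the rest posture (s = 0)
    i = min(sign_change, key=lambda k: min(abs(grid[k]), abs(grid[k + 1])))
    return float(brentq(height, grid[i], grid[i + 1], xtol=1e-12))


def _oriented_direction(model: ArmGroundTruth, direction: np.ndarray) -> np.ndarray:
    """Normalize and orient a synergy direction so +s raises the hammer."""
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("synergy direction must be nonzero")
    d = d / norm
    rest = model.rest_angles_deg
    dz = _wp_height(model, rest + 1e-3 * d) - _wp_height(model, rest)
    return -d if dz < 0 else d


@dataclass
class StrikePlan:
    """Targets and synergy structure of one generated strike.

    ``secondary`` holds ``(seed_vector, variance_ratio)`` pairs: each seed is
    projected into the task null space of the realized strike path (orthogonal
    to the primary direction and to the working-point/hand height gradients
    along the path) before use, so secondary joint covariation leaves the
    hammer's vertical trajectory essentially unchanged.
    """

    target_ek: float  # J, peak working-point kinetic energy
    target_ep: float  # J, potential energy at the apex relative to the surface
    direction: np.ndarray  # (9,) primary joint-space synergy (unit, oriented)
    secondary: list[tuple[np.ndarray, float]] = field(default_factory=list)
    # list of (seed vector, variance ratio relative to the primary)
    raise_duration: float = 0.5
    recover_duration: float = 0.5
    pause_duration: float = 0.3


@dataclass
class StrikeTruth:
    """Ground-truth ledger entry for one generated strike."""

    apex_frame: int
    contact_frame: int
    apex_wp_height: float  # m, world z of the working point at the apex
    ep: float  # J = m g (apex height - surface height)
    v_max: float  # m/s, true peak working-point speed (densely sampled)
    ek_max: float  # J = 1/2 m v_max^2
    target_ek: float
    target_ep: float
    direction: np.ndarray
    strike_frames: tuple[int, int]  # [apex, end-of-descent] frame range


def _secondary_courses(tau: np.ndarray, k: int) -> np.ndarray:
    """Smooth slow bump time courses vanishing (value and slope) at both
    ends. Deliberately low frequency: within a ~0.2 s descent a fast wiggle
    of the required angular variance would add unphysical hand speeds."""
    env = np.sin(np.pi * tau) ** 2
    if k == 0:
        return env
    return env * np.cos(k * np.pi * tau)


def _project_secondary(
    pairs: Sequence[tuple[np.ndarray, float]], avoid: Sequence[np.ndarray]
) -> list[tuple[np.ndarray, float]]:
    """Project secondary seed vectors onto the orthogonal complement of
    ``avoid`` (and of each other); seeds that vanish there are dropped."""
    basis: list[np.ndarray] = []
    for a in avoid:
        v = np.asarray(a, dtype=float).copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-9:
            basis.append(v / n)
    out: list[tuple[np.ndarray, float]] = []
    for seed, ratio in pairs:
        v = np.asarray(seed, dtype=float).copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-8:
            v = v / n
            basis.append(v)
            out.append((v, ratio))
    return out


def build_strike_trial(
    model: ArmGroundTruth,
    plans: Sequence[StrikePlan],
    fs: float = 240.0,
    sedentary_duration: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[JointTrajectory, list[StrikeTruth]]:
    """Assemble a trial: sedentary rest, then for each strike a raise to the
    apex posture, a minimum-jerk descent to surface contact, a recovery back
    to rest and a short pause.

    The apex posture is solved so the working point sits ``target_ep/(m g)``
    above the striking surface; the descent duration is solved so the true
    peak working-point speed equals ``sqrt(2 target_ek / m)`` (exact up to
    rounding the duration to whole frames). Ground truth is measured from
    the realized noiseless trajectory (8x oversampled), not from the
    targets, so the ledger is exact regardless of rounding.
    """
    dt = 1.0 / fs
    rest = model.rest_angles_deg
    surface = model.core_surface_height
    segments: list[np.ndarray] = [np.tile(rest, (int(round(sedentary_duration * fs)), 1))]
    truths: list[StrikeTruth] = []
    cursor = segments[0].shape[0]

    for plan in plans:
        h = plan.target_ep / (model.hammer_mass * GRAVITY)
        # a heavily jittered synergy direction may not reach the apex or the
        # surface; blend toward the template until the strike is reachable
        template = _oriented_direction(model, _TEMPLATE_DIRECTION)
        d = s_apex = s_contact = None
        for w in (0.0, 0.3, 0.5, 0.7, 0.9, 1.0):
            d_try = _oriented_direction(model, (1 - w) * plan.direction + w * template)
            try:
                s_apex = _solve_posture_scale(model, d_try, surface + h, (0.0, 250.0))
                s_contact = _solve_posture_scale(model, d_try, surface, (0.0, -250.0))
                d = d_try
                break
            except ValueError:
                continue
        if d is None:
            raise ValueError(
                "no reachable strike direction: the requested apex height or "
                "surface contact is outside the arm's workspace"
            )

        # project the secondary seeds into the task null space of this path:
        # orthogonal to the primary and to the vertical-height gradients of
        # working point and hand sensor at three postures along the descent
        avoid: list[np.ndarray] = [d]
        check_postures = np.array(
            [rest + s_chk * d for s_chk in (s_contact, 0.5 * (s_apex + s_contact), s_apex)]
        )
        for g_wp, g_hand in _height_gradients(model, check_postures):
            avoid.append(g_wp)
            avoid.append(g_hand)
        secondary = _project_secondary(plan.secondary, avoid)
        # a well-formed strike touches the stone only at its end and peaks at
        # its apex; shrink the secondary amplitude until the realized path
        # satisfies that (the task-null projection is only first order)
        tau_chk = np.linspace(0.0, 1.0, 160)
        for _ in range(8):
            if not secondary:
                break
            ang_chk = _descent_angles(rest, d, s_apex, s_contact, secondary, tau_chk)
            wp_z, hand_z = _heights_batch(model, ang_chk)
            penetrates = np.any(wp_z < surface - 0.005)
            above_apex = np.any(hand_z[8:] > hand_z[0] + 0.002)
            interior = (tau_chk > 0.02) & (tau_chk < 0.95)
            dips = (
                (np.r_[False, np.diff(hand_z) < 0] & np.r_[np.diff(hand_z) > 0, False])
                & interior
                & (wp_z - surface < 0.07)
            )
            if not (penetrates or above_apex or np.any(dips)):
                break
            secondary = [(b_dir, 0.4 * ratio) for b_dir, ratio in secondary]
        else:
            secondary = []

        n_raise = max(int(round(plan.raise_duration * fs)), 4)
        tau_r = np.arange(1, n_raise + 1) / n_raise
        raise_seg = rest + np.outer(minimum_jerk(tau_r) * s_apex, d)
        segments.append(raise_seg)
        apex_frame = cursor + n_raise - 1
        cursor += n_raise

        # descent duration from the exact 1/T speed scaling of a fixed
        # geometric joint path under uniform time reparametrization
        v_target = math.sqrt(2.0 * plan.target_ek / model.hammer_mass)
        t0 = 0.3
        v0 = _peak_wp_speed(model, d, s_apex, s_contact, secondary, t0, fs * 8)
        t_strike = t0 * v0 / v_target
        n_strike = max(int(round(t_strike * fs)), 6)

        tau_s = np.arange(1, n_strike + 1) / n_strike
        strike_seg = _descent_angles(rest, d, s_apex, s_contact, secondary, tau_s)
        segments.append(strike_seg)
        contact_frame = cursor + n_strike - 1

        # exact truth from a densely sampled noiseless copy of the descent
        v_max = _realized_peak_speed(
            model, rest, d, s_apex, s_contact, secondary, n_strike / fs, fs * 8
        )
        apex_height = _wp_height(model, rest + s_apex * d)
        truths.append(
            StrikeTruth(
                apex_frame=apex_frame,
                contact_frame=contact_frame,
                apex_wp_height=apex_height,
                ep=model.hammer_mass * GRAVITY * (apex_height - surface),
                v_max=v_max,
                ek_max=0.5 * model.hammer_mass * v_max**2,
                target_ek=plan.target_ek,
                target_ep=plan.target_ep,
                direction=d,
                strike_frames=(apex_frame, contact_frame),
            )
        )
        cursor += n_strike

        n_rec = max(int(round(plan.recover_duration * fs)), 4)
        tau_c = np.arange(1, n_rec + 1) / n_rec
        recover_seg = rest + np.outer(s_contact * (1 - minimum_jerk(tau_c)), d)
        segments.append(recover_seg)
        cursor += n_rec

        n_pause = max(int(round(plan.pause_duration * fs)), 2)
        segments.append(np.tile(rest, (n_pause, 1)))
        cursor += n_pause

    angles = np.vstack(segments)
    return JointTrajectory(fs=fs, angles_deg=angles), truths


def _descent_angles(
    rest: np.ndarray,
    d: np.ndarray,
    s_apex: float,
    s_contact: float,
    secondary: list[tuple[np.ndarray, float]],
    tau: np.ndarray,
) -> np.ndarray:
    path = s_apex + (s_contact - s_apex) * minimum_jerk(tau)
    ang = rest + np.outer(path, d)
    sigma_s = float(np.std(path))
    for k, (b_dir, ratio) in enumerate(secondary):
        course = _secondary_courses(tau, k)
        course_sd = float(np.std(course))
        if course_sd > 0:
            scale = math.sqrt(max(ratio, 0.0)) * sigma_s / course_sd
            ang = ang + np.outer(scale * course, b_dir)
    return ang


def _peak_wp_speed(model, d, s_apex, s_contact, secondary, duration, fs_dense) -> float:
    return _realized_peak_speed(
        model, model.rest_angles_deg, d, s_apex, s_contact, secondary, duration, fs_dense
    )


def _realized_peak_speed(
    model, rest, d, s_apex, s_contact, secondary, duration, fs_dense
) -> float:
    n = max(int(round(duration * fs_dense)), 32)
    tau = np.arange(n + 1) / n
    ang = _descent_angles(rest, d, s_apex, s_contact, secondary, tau)
    traj = JointTrajectory(fs=n / duration, angles_deg=ang)
    wp = forward_kinematics(model, traj).working_point
    vel = np.gradient(wp, duration / n, axis=0)
    return float(np.max(np.linalg.norm(vel, axis=1)))


def make_circumduction_trial(
    model: ArmGroundTruth,
    fs: float = 240.0,
    duration: float = 5.0,
    max_amplitude_deg: float = 40.0,
) -> JointTrajectory:
    """Shoulder calibration movement: an expanding flexion/abduction spiral
    (amplitude ramp avoids a planar arc, which would make the sphere fit
    degenerate), elbow and wrist held at rest."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ramp = np.sin(np.pi * t / duration) ** 2 * max_amplitude_deg
    ang = np.tile(model.rest_angles_deg, (n, 1))
    ang[:, 0] += ramp * np.sin(2 * np.pi * 0.9 * t)
    ang[:, 1] += ramp * np.cos(2 * np.pi * 0.9 * t)
    return JointTrajectory(fs=fs, angles_deg=ang)


def make_ballistic_trial(
    model: ArmGroundTruth,
    fs: float = 240.0,
    drop_time: float = 0.25,
    raise_duration: float = 1.0,
    sedentary_duration: float = 1.0,
) -> tuple[JointTrajectory, StrikeTruth]:
    """Pure gravity-drop oracle trial.

    The arm is raised to an apex posture whose working-point height is
    exactly ``h = g T^2 / 2`` above the surface with ``T`` a whole number of
    frames, then the whole body free-falls rigidly (joint angles frozen).
    The surface crossing lands exactly on the sample grid and free fall
    continues one frame past it before holding, so 240 Hz central
    differences recover the crossing speed ``g T = sqrt(2 g h)`` exactly:
    the measured Ek/Ep ratio of this strike is 1 to float precision.
    """
    dt = 1.0 / fs
    n_drop = int(round(drop_time * fs))
    t_drop = n_drop * dt
    h = 0.5 * GRAVITY * t_drop**2
    d = _oriented_direction(model, _TEMPLATE_DIRECTION)
    s_apex = _solve_posture_scale(
        model, d, model.core_surface_height + h, (0.0, 250.0)
    )
    rest = model.rest_angles_deg
    apex = rest + s_apex * d

    n_sed = int(round(sedentary_duration * fs))
    n_raise = max(int(round(raise_duration * fs)), 4)
    tau_r = np.arange(1, n_raise + 1) / n_raise
    raise_seg = rest + np.outer(minimum_jerk(tau_r) * s_apex, d)
    n_hold = int(round(0.5 * fs))

    k = np.arange(1, n_drop + 2)  # free fall continues one frame past contact
    drop_z = -0.5 * GRAVITY * (k * dt) ** 2
    n_total = n_sed + n_raise + len(k) + n_hold
    angles = np.vstack(
        [
            np.tile(rest, (n_sed, 1)),
            raise_seg,
            np.tile(apex, (len(k) + n_hold, 1)),
        ]
    )
    base = np.zeros((n_total, 3))
    start_drop = n_sed + n_raise
    base[start_drop : start_drop + len(k), 2] = drop_z
    base[start_drop + len(k) :, 2] = drop_z[-1]

    apex_frame = n_sed + n_raise - 1
    contact_frame = apex_frame + n_drop
    apex_height = _wp_height(model, apex)
    v_true = GRAVITY * t_drop
    truth = StrikeTruth(
        apex_frame=apex_frame,
        contact_frame=contact_frame,
        apex_wp_height=apex_height,
        ep=model.hammer_mass * GRAVITY * (apex_height - model.core_surface_height),
        v_max=v_true,
        ek_max=0.5 * model.hammer_mass * v_true**2,
        target_ek=0.5 * model.hammer_mass * v_true**2,
        target_ep=model.hammer_mass * GRAVITY * h,
        direction=d,
        strike_frames=(apex_frame, contact_frame + 1),
    )
    return JointTrajectory(fs=fs, angles_deg=angles, base_translation=base), truth


# ---------------------------------------------------------------------------
# outcome (flake mass) model
# ---------------------------------------------------------------------------


def energy_mass_response(ek: np.ndarray, e_half: float = 2.0) -> np.ndarray:
    """Saturating monotone response of flake mass to delivered kinetic energy."""
    ek = np.asarray(ek, dtype=float)
    return ek / (ek + e_half)


@dataclass
class GroupSpec:
    """Generator parameters of one expertise group.

    Energy means/SDs are in joules; flake-mass medians in grams. The
    within/between lognormal sigmas split flake-mass dispersion into
    within-subject regularity and between-subject style, mirroring the
    group-level SD and per-subject average CV structure of the study's
    outcome table.
    """

    name: str
    n_subjects: int
    ek_mean: float
    ek_sd: float
    ep_mean: float
    ep_sd: float
    avg_strikes_per_flake: float
    mass_median_small: float  # g, small-flake conditions
    mass_median_large: float  # g, large-flake conditions
    mass_sigma_within: float  # lognormal sigma, within subject
    mass_sigma_between: float  # lognormal sigma, between subjects
    pc_fracs: tuple[float, float, float]  # target per-strike variance fractions
    loading_jitter: float = 0.9

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("subject count must be >= 1")
        for nm in ("ek_sd", "ep_sd", "mass_sigma_within", "mass_sigma_between"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        for nm in ("ek_mean", "ep_mean", "mass_median_small", "mass_median_large"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        if not 1.0 <= self.avg_strikes_per_flake <= 3.0:
            raise ValueError("avg_strikes_per_flake must lie in [1, 3]")

    @property
    def strike_success_prob(self) -> float:
        """Per-strike flake probability p reproducing the group's average
        number of strikes per *produced* flake under the three-strike rule:
        E[strikes per attempt] / P(attempt succeeds)
        = (3 - 3p + p^2) / (1 - (1-p)^3) = avg_strikes_per_flake."""
        e = self.avg_strikes_per_flake

        def f(p: float) -> float:
            return (3.0 - 3.0 * p + p * p) / (1.0 - (1.0 - p) ** 3) - e

        if e <= 1.0:
            return 1.0
        return float(brentq(f, 1e-6, 1 - 1e-9))

    @property
    def secondary_ratios(self) -> tuple[float, float]:
        f1, f2, f3 = self.pc_fracs
        return (f2 / f1, f3 / f1)


@dataclass
class CohortSpec:
    """Synthetic study design: groups, task structure and measurement model."""

    groups: list[GroupSpec]
    fs: float = 240.0
    flakes_per_condition: int = 3
    max_strikes_per_flake: int = 3
    artifact_amplitude: float = 0.004  # m, soft-tissue drift peak
    noise_sd: float = 1e-4  # m, white position noise
    analyzed_condition: str = "small_600g"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


def default_cohort_spec() -> CohortSpec:
    """The study conditions: four expertise groups of 6/6/3/4 subjects whose
    energy profiles, strike economy and flake-mass dispersion mirror the
    published group summary of the task (small-flake production, 600 g
    hammer), with per-group PC1/PC2 variance shares mirroring the reported
    joint-angle variation structure."""
    return CohortSpec(
        groups=[
            GroupSpec(
                "uninitiated", 6, 12.30, 4.88, 3.39, 1.06, 2.2,
                3.5, 4.5, 0.85, 1.50, (0.64, 0.20, 0.16),
            ),
            GroupSpec(
                "novice", 6, 4.20, 1.27, 2.24, 0.47, 1.6,
                10.0, 15.0, 0.79, 0.82, (0.74, 0.17, 0.09),
            ),
            GroupSpec(
                "intermediate", 3, 5.21, 2.36, 2.13, 1.34, 1.3,
                8.0, 50.0, 0.83, 0.77, (0.75, 0.17, 0.08),
            ),
            GroupSpec(
                "expert", 4, 4.44, 2.56, 1.37, 0.45, 1.4,
                12.0, 50.0, 0.58, 0.675, (0.76, 0.16, 0.08),
            ),
        ]
    )


def simulate_flake_masses(
    group: GroupSpec,
    ek_per_strike: np.ndarray,
    rng: np.random.Generator,
    subject_ids: Optional[np.ndarray] = None,
    size: str = "small",
    failure_prob: float = 0.0,
    style_factor: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flake masses (g) for a set of strikes with delivered kinetic energies.

    mass = median * (f(Ek) / f(Ek_mean)) * exp(sigma_b Z_subject + sigma_w Z)
    with ``f`` a saturating monotone response, lognormal within-subject noise
    and a per-subject lognormal style factor. A strike fails to detach a
    flake with probability ``failure_prob`` (mass is NaN there).

    Returns ``(masses, produced)``.
    """
    ek = np.asarray(ek_per_strike, dtype=float)
    if np.any(ek < 0):
        raise ValueError("kinetic energies must be >= 0")
    median = group.mass_median_small if size == "small" else group.mass_median_large
    response = energy_mass_response(ek) / energy_mass_response(np.asarray(group.ek_mean))
    if subject_ids is None:
        subject_ids = np.zeros(len(ek), dtype=int)
    subject_ids = np.asarray(subject_ids)
    if style_factor is not None:
        style_arr = np.full(len(ek), float(style_factor))
    else:
        unique = np.unique(subject_ids)
        style = {
            s: math.exp(group.mass_sigma_between * rng.standard_normal()) for s in unique
        }
        style_arr = np.array([style[s] for s in subject_ids])
    noise = np.exp(group.mass_sigma_within * rng.standard_normal(len(ek)))
    masses = median * response * style_arr * noise
    produced = rng.random(len(ek)) >= failure_prob
    masses = np.where(produced, masses, np.nan)
    return masses, produced


# ---------------------------------------------------------------------------
# full cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Everything generated for one synthetic participant."""

    subject_id: str
    group: str
    model: ArmGroundTruth  # ground truth (not visible to the pipeline)
    calibration: CalibrationRecord
    shoulder_trial: TrialRecording  # circumduction used for the sphere fit
    task_trials: list[TrialRecording]  # one per flake attempt
    outcomes: list[OutcomeRecord]  # analyzed condition, per strike
    classification_outcomes: list[OutcomeRecord]  # all six conditions
    strike_truths: list[list[StrikeTruth]]  # per trial, per strike


@dataclass
class SyntheticStudy:
    """A complete simulated study with its ground-truth ledger."""

    spec: CohortSpec
    seed: int
    subjects: list[SubjectData]

    def truth_energy_table(self):
        """Ground-truth per-strike energies as plain records."""
        rows = []
        for sub in self.subjects:
            for trial_idx, truths in enumerate(sub.strike_truths, start=1):
                for strike_idx, tr in enumerate(truths, start=1):
                    rows.append(
                        {
                            "subject": sub.subject_id,
                            "group": sub.group,
                            "trial": trial_idx,
                            "strike": strike_idx,
                            "ek_max": tr.ek_max,
                            "ep": tr.ep,
                            "ratio": tr.ek_max / tr.ep if tr.ep > 0 else np.nan,
                        }
                    )
        return rows

    def write(self, outdir) -> None:
        """Write the whole study in the plain-text formats of :mod:`knapkin.io`."""
        from pathlib import Path

        from .io import write_calibration, write_outcomes, write_trial

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_outcomes: list[OutcomeRecord] = []
        all_class: list[OutcomeRecord] = []
        for sub in self.subjects:
            sdir = outdir / sub.subject_id
            sdir.mkdir(exist_ok=True)
            write_calibration(sub.calibration, sdir / "calibration.json")
            write_trial(sub.shoulder_trial, sdir / "shoulder_calibration.csv")
            for i, rec in enumerate(sub.task_trials, start=1):
                write_trial(rec, sdir / f"trial_{i:02d}.csv")
            all_outcomes.extend(sub.outcomes)
            all_class.extend(sub.classification_outcomes)
        write_outcomes(all_outcomes, outdir / "outcomes.json")
        write_outcomes(all_class, outdir / "classification_outcomes.json")
        manifest = {
            "format": "knapkin-study v1",
            "seed": self.seed,
            "subjects": {
                s.subject_id: {"group": s.group, "n_trials": len(s.task_trials)}
                for s in self.subjects
            },
        }
        import json

        (outdir / "study.json").write_text(json.dumps(manifest, indent=1))


# reachable-range truncation for energy draws: Ep below ~0.7 J would put the
# apex inside the rest clearance; above ~5.0 J outside the arm's reach
_EK_RANGE = (0.5, np.inf)
_EP_RANGE = (0.7, 5.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float = np.inf
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(lo + 1e-6, mean), hi - 1e-6 if np.isfinite(hi) else mean))


def _random_orthonormal_to(
    rng: np.random.Generator, avoid: Sequence[np.ndarray], k: int
) -> list[np.ndarray]:
    """``k`` random orthonormal vectors orthogonal to every vector in ``avoid``."""
    basis: list[np.ndarray] = []
    for a in avoid:
        v = np.asarray(a, dtype=float).copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-9:
            basis.append(v / n)
    out: list[np.ndarray] = []
    while len(out) < k:
        v = rng.standard_normal(9)
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 1e-6:
            v /= n
            basis.append(v)
            out.append(v)
    return out


def _heights_batch(
    model: ArmGroundTruth, angles_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(working-point z, hand-sensor z) for a batch of postures; one FK call."""
    traj = JointTrajectory(fs=1.0, angles_deg=np.atleast_2d(angles_matrix))
    frames = forward_kinematics(model, traj)
    return frames.working_point[:, 2], frames.sensors["hand"][0][:, 2]


def _hand_sensor_height(model: ArmGroundTruth, angles: np.ndarray) -> float:
    return float(_heights_batch(model, angles[None, :])[1][0])


def _height_gradients(
    model: ArmGroundTruth, postures: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-posture gradients (d wp_z/d phi, d hand_z/d phi) by central
    differences, all postures and channels in a single batched FK call."""
    postures = np.atleast_2d(postures)
    eps = 1e-4
    batch = []
    for p in postures:
        for i in range(9):
            up = p.copy()
            dn = p.copy()
            up[i] += eps
            dn[i] -= eps
            batch.append(up)
            batch.append(dn)
    wp_z, hand_z = _heights_batch(model, np.array(batch))
    out = []
    for k in range(len(postures)):
        base = 18 * k
        g_wp = (wp_z[base : base + 18 : 2] - wp_z[base + 1 : base + 18 : 2]) / (2 * eps)
        g_hand = (hand_z[base : base + 18 : 2] - hand_z[base + 1 : base + 18 : 2]) / (
            2 * eps
        )
        out.append((g_wp, g_hand))
    return out


def task_null_directions(
    model: ArmGroundTruth,
    primary: np.ndarray,
    rng: np.random.Generator,
    k: int = 2,
) -> list[np.ndarray]:
    """Secondary synergy directions in the task null space: orthogonal to
    the primary direction *and* to the vertical-height gradients of both the
    working point and the hand sensor at rest, so elemental joint
    variability leaves the hammer's vertical trajectory (the task variable)
    first-order invariant — variable joints, stable working point."""
    (g_wp, g_hand), = _height_gradients(model, model.rest_angles_deg)
    return _random_orthonormal_to(rng, [primary, g_wp, g_hand], k)


def draw_strike_direction(
    model: ArmGroundTruth,
    template: np.ndarray,
    jitter: float,
    rng: np.random.Generator,
    coupling: float = 0.5,
    max_tries: int = 60,
) -> np.ndarray:
    """A jittered per-strike synergy direction that is kinematically
    plausible for a percussive blow: along it, the hand sensor must descend
    together with the hammer working point (initial vertical coupling of at
    least ``coupling``, checked at the rest and a raised posture). Random
    jitter without this constraint produces pendulum-impossible strikes in
    which the hand rises while the hammer falls, which no knapper performs
    and which would defeat the apex-based movement-start rule downstream."""
    rest = model.rest_angles_deg
    for _ in range(max_tries):
        d = _oriented_direction(model, template + jitter * rng.standard_normal(9))
        ok = True
        for g_wp, g_hand in _height_gradients(model, np.array([rest, rest + 30.0 * d])):
            if g_wp @ d <= 0 or g_hand @ d < coupling * (g_wp @ d):
                ok = False
                break
        if ok:
            return d
    return _oriented_direction(model, template)


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticStudy:
    """Generate a full synthetic study in the study's task structure: per
    subject, a stylus calibration, a shoulder circumduction trial, and one
    motion trial per flake attempt (up to three strikes each, stopping at
    the first success) in the analyzed condition, plus outcome records for
    the remaining size/hammer conditions used only for skill allocation.

    Deterministic for a given ``(spec, seed)``.
    """
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(spec.n_subjects)
    subjects: list[SubjectData] = []
    sid = 0
    all_conditions = [
        ("small", 0.4, "small_400g"),
        ("small", 0.6, "small_600g"),
        ("small", 0.8, "small_800g"),
        ("large", 0.4, "large_400g"),
        ("large", 0.6, "large_600g"),
        ("large", 0.8, "large_800g"),
    ]
    for group in spec.groups:
        for _ in range(group.n_subjects):
            sid += 1
            rng = np.random.default_rng(subject_seeds[sid - 1])
            subject_id = f"P{sid:02d}"
            model = make_arm_model(
                (
                    rng.normal(0.30, 0.015),
                    rng.normal(0.26, 0.012),
                    rng.normal(0.08, 0.004),
                ),
                hammer_spec={"mass": 0.6},
            )
            calibration = simulate_stylus_calibration(model)
            shoulder_frames = forward_kinematics(
                model, make_circumduction_trial(model, fs=spec.fs)
            )
            shoulder_trial = render_sensor_tracks(
                shoulder_frames,
                model,
                artifact_amplitude=spec.artifact_amplitude * 0.25,
                noise_sd=spec.noise_sd,
                rng=rng,
                condition="shoulder_calibration",
                subject=subject_id,
                trial=0,
            )
            template = _TEMPLATE_DIRECTION + 0.25 * rng.standard_normal(9)
            # per-subject flake-mass "style": persistent between-subject factor
            style = {
                "small": math.exp(group.mass_sigma_between * rng.standard_normal()),
                "large": math.exp(group.mass_sigma_between * rng.standard_normal()),
            }

            task_trials: list[TrialRecording] = []
            outcomes: list[OutcomeRecord] = []
            strike_truths: list[list[StrikeTruth]] = []
            p_success = group.strike_success_prob
            for attempt in range(1, spec.flakes_per_condition + 1):
                n_strikes = 1
                while (
                    n_strikes < spec.max_strikes_per_flake
                    and rng.random() >= p_success
                ):
                    n_strikes += 1
                success_flags = [False] * n_strikes
                # the attempt ends either on a success or after max strikes
                if n_strikes < spec.max_strikes_per_flake or rng.random() < p_success:
                    success_flags[-1] = True
                plans = []
                for _ in range(n_strikes):
                    d = draw_strike_direction(model, template, group.loading_jitter, rng)
                    r2, r3 = group.secondary_ratios
                    b = task_null_directions(model, d, rng, 2)
                    plans.append(
                        StrikePlan(
                            target_ek=_truncated_normal(
                                rng, group.ek_mean, group.ek_sd, *_EK_RANGE
                            ),
                            target_ep=_truncated_normal(
                                rng, group.ep_mean, group.ep_sd, *_EP_RANGE
                            ),
                            direction=d,
                            secondary=[(b[0], r2), (b[1], r3)],
                        )
                    )
                traj, truths = build_strike_trial(model, plans, fs=spec.fs)
                frames = forward_kinematics(model, traj)
                rec = render_sensor_tracks(
                    frames,
                    model,
                    artifact_amplitude=spec.artifact_amplitude,
                    noise_sd=spec.noise_sd,
                    rng=rng,
                    condition=spec.analyzed_condition,
                    subject=subject_id,
                    trial=attempt,
                )
                task_trials.append(rec)
                strike_truths.append(truths)
                ek_true = np.array([tr.ek_max for tr in truths])
                masses, _ = simulate_flake_masses(
                    group, ek_true, rng, size="small", style_factor=style["small"]
                )
                for k in range(n_strikes):
                    outcomes.append(
                        OutcomeRecord(
                            subject=subject_id,
                            condition=spec.analyzed_condition,
                            trial=attempt,
                            strike_index=k + 1,
                            flake_produced=success_flags[k],
                            flake_mass_g=float(masses[k]) if success_flags[k] else None,
                            group=group.name,
                        )
                    )

            class_outcomes: list[OutcomeRecord] = []
            for size, hammer, cond in all_conditions:
                if cond == spec.analyzed_condition:
                    # the analyzed condition's outcomes feed classification too
                    class_outcomes.extend(outcomes)
                    continue
                n_flakes = spec.flakes_per_condition
                ek = np.array(
                    [
                        _truncated_normal(rng, group.ek_mean, group.ek_sd, *_EK_RANGE)
                        for _ in range(n_flakes)
                    ]
                )
                masses, _ = simulate_flake_masses(
                    group, ek, rng, size=size, style_factor=style[size]
                )
                for k in range(n_flakes):
                    class_outcomes.append(
                        OutcomeRecord(
                            subject=subject_id,
                            condition=cond,
                            trial=k + 1,
                            strike_index=1,
                            flake_produced=True,
                            flake_mass_g=float(masses[k]),
                            group=group.name,
                        )
                    )

            subjects.append(
                SubjectData(
                    subject_id=subject_id,
                    group=group.name,
                    model=model,
                    calibration=calibration,
                    shoulder_trial=shoulder_trial,
                    task_trials=task_trials,
                    outcomes=outcomes,
                    classification_outcomes=class_outcomes,
                    strike_truths=strike_truths,
                )
            )
    return SyntheticStudy(spec=spec, seed=seed, subjects=subjects)
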