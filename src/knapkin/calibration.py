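"""Subject-specific anatomical calibration (CAST stage).

Builds the :class:`LimbModel` that later drives per-frame reconstruction:
landmark offsets in adjacent-sensor frames from stylus records, the
glenohumeral joint center by sphere fitting a humerus-fixed point expressed
in the scapula-sensor frame, elbow/wrist centers as epicondyle/styloid
midpoints, and the registered hammer working point and core striking
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import invert_pose, rotation_from_quat
from .io import CalibrationRecord, LandmarkRecord, TrialRecording


class DegenerateFitError(ValueError):
    """Raised when a geometric fit has no unique solution."""


# ---------------------------------------------------------------------------
# stylus offsets
# ---------------------------------------------------------------------------


def landmark_offsets(
    stylus_points: dict[str, np.ndarray],
    sensor_pose_at_capture: dict[str, tuple[np.ndarray, np.ndarray]],
    reference_sensor: dict[str, str],
) -> dict[str, LandmarkRecord]:
    """Express globally recorded stylus points in their reference sensor
    frames: ``offset = R(q)^-1 (x_global - p_sensor)``.

    ``stylus_points`` maps landmark name to the global stylus tip position
    captured simultaneously with ``sensor_pose_at_capture`` (sensor ->
    ``(p, q)`` at that instant).
    """
    out: dict[str, LandmarkRecord] = {}
    for name, point in stylus_points.items():
        sensor = reference_sensor[name]
        p, q = sensor_pose_at_capture[sensor]
        out[name] = LandmarkRecord(sensor, invert_pose(p, q, np.asarray(point, float)))
    return out


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


def _check_not_coplanar(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0 or svals[-1] < 1e-8 * svals[0]:
        raise DegenerateFitError(
            "sphere fit is degenerate: points are (near-)coplanar; "
            "a larger calibration movement is needed"
        )


def fit_sphere(
    points: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (Kasa) initialization solved from the linear normal equations,
    refined by Gauss-Newton minimization of the geometric residual
    ``sum (||p_i - c|| - r)^2``. Returns ``(center, radius, rms_residual)``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if len(points) < 4:
        raise DegenerateFitError("sphere fit needs at least 4 points")
    _check_not_coplanar(points)

    # Kasa: |p|^2 = 2 p.c + (r^2 - |c|^2)
    a = np.hstack([2 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    radius = float(np.sqrt(max(r2, 0.0)))

    for _ in range(max_iter):
        diff = points - center
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist == 0):
            break
        res = dist - radius
        # Jacobian of residual wrt (c, r): [-(p_i - c)/d_i, -1]
        jac = np.hstack([-diff / dist[:, None], -np.ones((len(points), 1))])
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
        center = center + step[:3]
        radius = float(radius + step[3])
        if np.linalg.norm(step) < tol:
            break
    dist = np.linalg.norm(points - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return center, radius, rms


def estimate_shoulder_center(
    calibration_motion: TrialRecording,
    acromion_offset: Optional[np.ndarray] = None,
    moving_sensor: str = "upper_arm",
    reference_sensor: str = "scapula",
) -> dict:
    """Glenohumeral joint center by the sphere-fitting method.

    While the upper arm sweeps an arc and the scapula stays quasi-static,
    the upper-arm sensor origin (a humerus-fixed point) is expressed in the
    scapula-sensor frame each frame; that point cloud lies on a sphere
    centered at the joint center. Returns the center offset in the
    scapula-sensor frame, the fit radius/residual, and — when the acromion
    stylus offset is supplied — the center relative to the acromion.
    """
    mov = calibration_motion.tracks[moving_sensor]
    ref = calibration_motion.tracks[reference_sensor]
    rot = rotation_from_quat(ref.quat)
    cloud = rot.inv().apply(mov.pos - ref.pos)
    try:
        center, radius, rms = fit_sphere(cloud)
    except DegenerateFitError as exc:
        raise DegenerateFitError(
            "shoulder sphere fit failed: the calibration arc is too small or "
            "planar; record a wider circumduction movement"
        ) from exc
    out = {
        "center_offset": center,  # scapula-sensor frame
        "radius": radius,
        "rms_residual": rms,
        "n_frames": len(cloud),
    }
    if acromion_offset is not None:
        out["center_from_acromion"] = center - np.asarray(acromion_offset, float)
    return out


def midpoint_center(landmark_a: np.ndarray, landmark_b: np.ndarray) -> np.ndarray:
    """Joint center as the midpoint of a bony-landmark axis (epicondyles at
    the elbow, styloid processes at the wrist). Coincident landmarks still
    return the point (the axis is then undefined, which only matters for
    frame construction, handled there)."""
    return 0.5 * (np.asarray(landmark_a, float) + np.asarray(landmark_b, float))


# ---------------------------------------------------------------------------
# tool / surface registration
# ---------------------------------------------------------------------------


@dataclass
class SurfacePlane:
    """Striking-surface plane: a point and unit normal, in some frame."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / norm


def register_tool_and_surface(
    cal: CalibrationRecord,
) -> tuple[LandmarkRecord, SurfacePlane]:
    """Working-point offset (hand-sensor frame) and the striking-surface
    plane fitted to the stylus points (core-base-sensor frame).

    The plane is the total-least-squares fit: centroid plus the singular
    vector of smallest singular value; the normal is oriented toward +z of
    the sensor frame. Fewer than 3 or collinear points are rejected.
    """
    pts = np.array([rec.offset for rec in cal.surface_points], dtype=float)
    if len(pts) < 3:
        raise DegenerateFitError("surface registration needs >= 3 stylus points")
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * svals[0]:
        raise DegenerateFitError("surface stylus points are collinear; plane undefined")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    return cal.working_point, SurfacePlane(pts.mean(axis=0), normal)


# ---------------------------------------------------------------------------
# the subject model
# ---------------------------------------------------------------------------


@dataclass
class LimbModel:
    """Subject-specific calibration product consumed by reconstruction."""

    landmark_offsets: dict[str, LandmarkRecord]
    shoulder_offset: np.ndarray  # scapula-sensor frame
    working_point_offset: LandmarkRecord  # hand-sensor frame
    striking_surface: SurfacePlane  # core-base-sensor frame
    reference_segment_lengths: dict[str, float] = field(default_factory=dict)
    shoulder_fit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shoulder_offset = np.asarray(self.shoulder_offset, dtype=float)

    def validate(self) -> None:
        for name, rec in self.landmark_offsets.items():
            if not np.all(np.isfinite(rec.offset)):
                raise ValueError(f"non-finite offset for landmark '{name}'")
        for name, length in self.reference_segment_lengths.items():
            if not length > 0:
                raise ValueError(f"reference segment length '{name}' must be > 0")


def build_limb_model(
    cal: CalibrationRecord, shoulder_motion: TrialRecording
) -> LimbModel:
    """Assemble the full CAST product from a stylus record and a shoulder
    calibration movement. Reference segment lengths are filled later from a
    sedentary window of an actual recording."""
    acr = cal.landmarks.get("acromion")
    fit = estimate_shoulder_center(
        shoulder_motion,
        acromion_offset=None if acr is None else acr.offset,
    )
    wp, plane = register_tool_and_surface(cal)
    model = LimbModel(
        landmark_offsets=dict(cal.landmarks),
        shoulder_offset=fit["center_offset"],
        working_point_offset=wp,
        striking_surface=plane,
        shoulder_fit={k: fit[k] for k in ("radius", "rms_residual", "n_frames")},
    )
    model.validate()
    return model
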