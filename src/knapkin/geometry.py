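"""Rigid-body geometry helpers.

Conventions used throughout the package:

* right-handed world frame, units of meters, vertical axis = +Z;
* quaternions are scalar-first ``(qw, qx, qy, qz)`` and unit norm;
* a pose ``(p, q)`` maps local coordinates ``x`` to world coordinates via
  ``p + R(q) @ x``.

These helpers wrap :class:`scipy.spatial.transform.Rotation`; they exist so
that the scalar-first file convention is enforced in exactly one place.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

QUAT_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def rotation_from_quat(q: np.ndarray) -> Rotation:
    """Build a Rotation from scalar-first quaternion(s), shape (4,) or (n, 4)."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True)


def quat_from_rotation(r: Rotation) -> np.ndarray:
    """Scalar-first unit quaternion(s) for a Rotation."""
    return r.as_quat(scalar_first=True)


def quat_norm_error(q: np.ndarray) -> np.ndarray:
    return np.abs(np.linalg.norm(np.asarray(q, dtype=float), axis=-1) - 1.0)


def apply_pose(p: np.ndarray, q: np.ndarray, local: np.ndarray) -> np.ndarray:
    """Map local coordinates to world: ``p + R(q) @ local``.

    Broadcasts over time: ``p`` (n,3) with ``q`` (n,4) and a fixed (3,)
    ``local`` yields an (n,3) trace.
    """
    p = np.asarray(p, dtype=float)
    return p + rotation_from_quat(q).apply(np.asarray(local, dtype=float))


def invert_pose(p: np.ndarray, q: np.ndarray, world: np.ndarray) -> np.ndarray:
    """Express world coordinates in the local frame of pose ``(p, q)``."""
    r = rotation_from_quat(q)
    return r.inv().apply(np.asarray(world, dtype=float) - np.asarray(p, dtype=float))


def compose_pose(
    p_a: np.ndarray, q_a: np.ndarray, p_b: np.ndarray, q_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Compose pose B (expressed in frame A) with pose A: result maps B-local to world."""
    r_a = rotation_from_quat(q_a)
    p = np.asarray(p_a, dtype=float) + r_a.apply(np.asarray(p_b, dtype=float))
    q = quat_from_rotation(r_a * rotation_from_quat(q_b))
    return p, q


def orthonormal_frame(y_axis: np.ndarray, z_hint: np.ndarray) -> np.ndarray:
    """Rotation matrix (columns x, y, z) with exact ``y`` and ``z`` built from a hint.

    ``z`` is the component of ``z_hint`` orthogonal to ``y`` (normalized);
    ``x = y × z`` completes the right-handed triad. Vectorized over leading
    axes: inputs (..., 3) give (..., 3, 3).
    """
    y = np.asarray(y_axis, dtype=float)
    y = y / np.linalg.norm(y, axis=-1, keepdims=True)
    z = np.asarray(z_hint, dtype=float)
    z = z - np.sum(z * y, axis=-1, keepdims=True) * y
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(nz < 1e-12):
        raise ValueError("z_hint is parallel to y_axis; frame is undefined")
    z = z / nz
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1], rest-to-rest.

    ``s(0)=0, s(1)=1`` with zero velocity and acceleration at both ends.
    """
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5
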