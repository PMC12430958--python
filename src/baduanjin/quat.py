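"""Quaternion rotation math for motion trajectories.

Euler angles from BVH files are converted to unit quaternions before any
distance computation, because Euler representations suffer gimbal lock
and axis-order singularities.  All quaternions here are scalar-first
``(w, x, y, z)``.  A rotation is represented twice on the unit sphere
(``q`` and ``-q``); every operation below is double-cover safe.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .bvh import JointHierarchy, MotionSequence

__all__ = [
    "euler_to_quaternion",
    "quat_distance",
    "quat_distance_matrix",
    "slerp",
    "convert_motion",
]

_VALID_ORDERS = {"XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX"}


def _check_order(order: str) -> str:
    if not isinstance(order, str) or order.upper() not in _VALID_ORDERS:
        raise ValueError(f"channel order must be a permutation of XYZ, got {order!r}")
    return order.upper()


def euler_to_quaternion(angles_deg, order: str) -> np.ndarray:
    """Convert Euler angles (degrees, intrinsic, in channel order) to a unit quaternion.

    Returns scalar-first ``(w, x, y, z)`` with ``w >= 0`` (canonical sign).
    ``angles_deg`` may also be an (N, 3) stack; the result is then (N, 4).
    """
    order = _check_order(order)
    angles = np.asarray(angles_deg, dtype=float)
    q = Rotation.from_euler(order, angles, degrees=True).as_quat()  # (x, y, z, w)
    q = np.atleast_2d(q)[:, [3, 0, 1, 2]]
    q = np.where(q[:, :1] < 0, -q, q)
    return q[0] if angles.ndim == 1 else q


def quat_distance(a, b) -> float:
    """Geodesic angle between two rotations, in radians within [0, pi].

    ``d = 2 * arccos(min(1, |<a, b>|))``; the absolute dot product makes
    the metric blind to the quaternion double cover, so ``d(q, -q) = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("quat_distance requires non-zero quaternions")
    d = abs(float(np.dot(a, b)) / (na * nb))
    # 2*arccos(|dot|) in the numerically stable arcsin form; dots within a
    # few ulp of 1 are the same rotation at double precision -> exactly 0
    if d > 1.0 - 4e-15:
        return 0.0
    return 4.0 * np.arcsin(np.sqrt((1.0 - d) / 2.0))


def quat_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise geodesic angles between two stacks of unit quaternions.

    ``a`` is (n, 4), ``b`` is (m, 4); returns (n, m).  Inputs are assumed
    unit-norm (as produced by :func:`convert_motion`).
    """
    dots = np.minimum(1.0, np.abs(a @ b.T) + 4e-15)  # ulp slack: d(q, q) = 0 exactly
    return 4.0 * np.arcsin(np.sqrt((1.0 - dots) / 2.0))


def slerp(a, b, t: float) -> np.ndarray:
    """Spherical linear interpolation between two unit quaternions.

    Walks the shortest arc (sign-corrects ``b`` when ``<a, b> < 0``) at
    constant angular velocity; ``t`` must lie in [0, 1].
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = float(np.dot(a, b))
    if dot < 0.0:
        b = -b
        dot = -dot
    dot = min(1.0, dot)
    theta = np.arccos(dot)
    if theta < 1e-10:
        out = (1 - t) * a + t * b  # nearly parallel: lerp is exact to rounding
    else:
        s = np.sin(theta)
        out = (np.sin((1 - t) * theta) / s) * a + (np.sin(t * theta) / s) * b
    return out / np.linalg.norm(out)


def convert_motion(m: MotionSequence, h: JointHierarchy) -> MotionSequence:
    """Attach unit quaternions to a Euler-angle motion.

    Each joint's angles are converted with that joint's declared channel
    order.  Frame 0 is canonicalized to ``w >= 0``; subsequent frames are
    sign-flipped whenever the dot product with the previous frame is
    negative, so each joint's trajectory is continuous on the 4-sphere
    (stable costs for DTW and valid slerp segments).
    """
    if m.euler_frames is None:
        raise ValueError("convert_motion requires euler_frames")
    if m.n_joints != h.n_joints:
        raise ValueError(f"joint count mismatch: motion {m.n_joints}, hierarchy {h.n_joints}")
    if any(not o for o in h.channel_order):
        raise ValueError("hierarchy is missing channel orders")

    F, J = m.n_frames, m.n_joints
    quat = np.empty((F, J, 4))
    for j in range(J):
        q = euler_to_quaternion(m.euler_frames[:, j, :], h.channel_order[j])
        q = np.atleast_2d(q)
        if q[0, 0] < 0:
            q[0] = -q[0]
        if F > 1:
            dots = np.einsum("ij,ij->i", q[1:], q[:-1])
            signs = np.cumprod(np.where(dots < 0, -1.0, 1.0))
            q[1:] *= signs[:, None]
        quat[:, j, :] = q
    return MotionSequence(
        frame_time=m.frame_time,
        euler_frames=m.euler_frames,
        quat_frames=quat,
        root_position=m.root_position,
    )
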