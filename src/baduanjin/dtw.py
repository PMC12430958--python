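"""Band-constrained dynamic time warping on quaternion trajectories.

Motion accuracy is scored as the DTW distance between a student capture
and an expert template: each of the 17 joints is aligned independently
(frame cost = geodesic quaternion angle, radians), and the 17 per-joint
distances are averaged.  The warping path is restricted to a Sakoe-Chiba
band whose half-width is 10% of the longer sequence by default, which
prevents pathological warps between motions of similar tempo.

The step pattern is the symmetric unweighted one (steps (1,0), (0,1),
(1,1), each visited cell contributing its cost once) and no path-length
normalization is applied: the captures being compared have comparable
durations, so raw summed cost orders skill levels directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bvh import MotionSequence
from .quat import quat_distance_matrix

__all__ = ["DTWResult", "dtw_joint", "motion_distance", "band_half_width"]


@dataclass
class DTWResult:
    """Per-joint DTW distances, their mean, and the optimal warping paths."""

    total_distance: float
    per_joint_distance: np.ndarray  # (J,)
    per_joint_path: list[list[tuple[int, int]]]


def band_half_width(n: int, m: int, band_fraction: float) -> int:
    """Sakoe-Chiba half-width: ceil(fraction * longer length), widened to
    at least |n - m| so the (n-1, m-1) corner stays reachable."""
    return max(math.ceil(band_fraction * max(n, m)), abs(n - m))


def dtw_joint(
    a: np.ndarray,
    b: np.ndarray,
    band_fraction: float = 0.10,
    cost: np.ndarray | None = None,
) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance and optimal path between two quaternion sequences.

    ``a`` (n, 4) and ``b`` (m, 4) are unit-quaternion trajectories of one
    joint.  Cells outside ``|i - j| <= band_half_width`` are forbidden.
    A precomputed ``cost`` matrix may be supplied to skip the pairwise
    angle computation.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("DTW requires non-empty sequences")
    if not 0.0 < band_fraction <= 1.0:
        raise ValueError(f"band_fraction must be in (0, 1], got {band_fraction}")
    if cost is None:
        cost = quat_distance_matrix(a, b)
    w = band_half_width(n, m, band_fraction)

    INF = np.inf
    D = np.full((n, m), INF)
    # backpointer codes: 0 = (i-1, j-1), 1 = (i-1, j), 2 = (i, j-1)
    back = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        lo = max(0, i - w)
        hi = min(m - 1, i + w)
        for j in range(lo, hi + 1):
            c = cost[i, j]
            if i == 0 and j == 0:
                D[0, 0] = c
                continue
            best = INF
            move = 0
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
                move = 0
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
                move = 1
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
                move = 2
            D[i, j] = best + c
            back[i, j] = move

    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        move = back[i, j]
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return float(D[n - 1, m - 1]), path


def motion_distance(
    student: MotionSequence,
    reference: MotionSequence,
    band_fraction: float = 0.10,
    keep_paths: bool = True,
) -> DTWResult:
    """Motion-accuracy distance: mean of the per-joint DTW distances.

    Both sequences must already carry quaternions for the same joint
    profile.  Larger totals mean less accurate execution relative to the
    reference (expert) capture.
    """
    if student.quat_frames is None or reference.quat_frames is None:
        raise ValueError("motion_distance requires quaternion-converted sequences")
    if student.n_joints != reference.n_joints:
        raise ValueError(
            f"joint count mismatch: {student.n_joints} vs {reference.n_joints}"
        )
    J = student.n_joints
    dists = np.empty(J)
    paths: list[list[tuple[int, int]]] = []
    for j in range(J):
        d, p = dtw_joint(
            student.quat_frames[:, j, :],
            reference.quat_frames[:, j, :],
            band_fraction=band_fraction,
        )
        dists[j] = d
        paths.append(p if keep_paths else [])
    return DTWResult(float(dists.mean()), dists, paths)
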