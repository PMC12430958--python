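"""Keyframe extraction by k-means and slerp reconstruction.

Motions are compressed to a preset fraction of their frames (15% by
default): frames are embedded as concatenated per-joint quaternions,
clustered with k-means, and each cluster is represented by the frame
nearest its centroid.  The first and last frames are always kept so the
whole duration can be reconstructed by per-joint spherical interpolation
between consecutive keyframes.  Reconstruction error is the mean
quaternion geodesic angle over all frames and joints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .bvh import MotionSequence
from .quat import quat_distance_matrix, slerp

__all__ = ["KeyframeSet", "extract_keyframes", "reconstruct", "reconstruction_error"]


@dataclass
class KeyframeSet:
    """Strictly increasing frame indices (first and last included) plus
    the compression ratio that produced them."""

    indices: np.ndarray
    ratio: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) < 2:
            raise ValueError("a keyframe set needs at least 2 frames")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("keyframe indices must be strictly increasing")
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError(f"ratio must be in (0, 1], got {self.ratio}")


def _frame_embedding(m: MotionSequence) -> np.ndarray:
    # (F, J*4) sign-continuous quaternion coordinates
    F = m.n_frames
    return m.quat_frames.reshape(F, -1)


def extract_keyframes(m: MotionSequence, ratio: float = 0.15, seed: int = 0) -> KeyframeSet:
    """Select ``max(2, round(ratio * F))`` keyframes by k-means clustering.

    k-means (k-means++ init, 10 restarts, seeded) runs on the quaternion
    frame embedding; per cluster the frame nearest the centroid is kept,
    then the earliest and latest selections are snapped to the first and
    last frame of the motion.
    """
    if m.quat_frames is None:
        raise ValueError("keyframe extraction requires quat_frames (convert the motion first)")
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    F = m.n_frames
    if F < 2:
        raise ValueError("keyframe extraction requires at least 2 frames")
    k = int(round(ratio * F))
    k = min(max(2, k), F)

    X = _frame_embedding(m)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(X)
    reps = []
    for c in range(k):
        members = np.flatnonzero(km.labels_ == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(members[np.argmin(d)]))
    reps = sorted(set(reps))
    # force-include the endpoints without changing the count
    reps[0] = 0
    reps[-1] = F - 1
    reps = sorted(set(reps))
    return KeyframeSet(np.array(reps), ratio)


def reconstruct(m: MotionSequence, k: KeyframeSet) -> MotionSequence:
    """Rebuild a full-length motion from its keyframes by per-joint slerp.

    Keyframe frames are reproduced exactly; frames between consecutive
    keyframes are interpolated at their original positions.  The result
    carries quaternions only (no Euler channels are reconstructed).
    """
    if m.quat_frames is None:
        raise ValueError("reconstruction requires quat_frames")
    F, J = m.n_frames, m.n_joints
    idx = k.indices
    if idx[0] < 0 or idx[-1] >= F:
        raise ValueError("keyframe indices out of range")
    out = np.empty_like(m.quat_frames)
    out[idx] = m.quat_frames[idx]
    for a, b in zip(idx[:-1], idx[1:]):
        span = b - a
        for f in range(a + 1, b):
            t = (f - a) / span
            for j in range(J):
                out[f, j] = slerp(m.quat_frames[a, j], m.quat_frames[b, j], t)
    # frames before the first / after the last keyframe cannot occur
    # (extract_keyframes pins the endpoints), but guard for hand-built sets
    out[: idx[0]] = m.quat_frames[idx[0]]
    out[idx[-1] + 1 :] = m.quat_frames[idx[-1]]
    return MotionSequence(frame_time=m.frame_time, quat_frames=out)


def reconstruction_error(original: MotionSequence, reconstructed: MotionSequence) -> float:
    """Mean geodesic angle (radians) between matching frames and joints."""
    if original.quat_frames is None or reconstructed.quat_frames is None:
        raise ValueError("reconstruction_error requires quat_frames on both motions")
    if original.quat_frames.shape != reconstructed.quat_frames.shape:
        raise ValueError("motions must have identical frame and joint counts")
    F, J, _ = original.quat_frames.shape
    a = original.quat_frames.reshape(F * J, 4)
    b = reconstructed.quat_frames.reshape(F * J, 4)
    dots = np.minimum(1.0, np.abs(np.einsum("ij,ij->i", a, b)) + 4e-15)
    return float(np.mean(4.0 * np.arcsin(np.sqrt((1.0 - dots) / 2.0))))
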