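"""Reading and writing Biovision Hierarchy (BVH) skeletal motion files.

A BVH document has two sections: HIERARCHY, a recursive declaration of
joints with translation offsets and per-joint channel lists, and MOTION,
a frame count, a frame time, and one whitespace-separated row of channel
values per frame.  Rotation channels are Euler angles in degrees, applied
intrinsically in the declared channel order.  Commercial IMU suits such
as the Perception Neuron export this format; the profile used here keeps
17 skeleton points.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BVHParseError",
    "JointHierarchy",
    "MotionSequence",
    "MotionSample",
    "PERCEPTION_NEURON_17",
    "parse_bvh",
    "write_bvh",
    "select_joints",
]

#: Default 17-joint capture profile (hips, spine x2, neck, head, and both
#: shoulder/upper-arm/forearm/hand and upper-leg/lower-leg chains).  Files
#: from other exporters can be subset to any configurable name list with
#: :func:`select_joints`.
PERCEPTION_NEURON_17 = (
    "Hips",
    "Spine",
    "Spine1",
    "Neck",
    "Head",
    "LeftShoulder",
    "LeftArm",
    "LeftForeArm",
    "LeftHand",
    "RightShoulder",
    "RightArm",
    "RightForeArm",
    "RightHand",
    "LeftUpLeg",
    "LeftLeg",
    "RightUpLeg",
    "RightLeg",
)

_ROT_LABEL = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}
_POS_LABELS = {"Xposition", "Yposition", "Zposition"}


class BVHParseError(ValueError):
    """Malformed BVH document; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class JointHierarchy:
    """Skeleton topology: joint names, parent links, offsets and channels.

    ``channel_order[j]`` is the rotation-axis permutation (e.g. ``"YXZ"``)
    in file order; ``channel_counts[j]`` is 6 when the joint also carries
    three translation channels (typically only the root), else 3.
    """

    joint_names: list[str]
    parent_index: list[int | None]
    offsets: np.ndarray  # (J, 3), centimetres, passed through untouched
    channel_order: list[str]
    channel_counts: list[int]

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(len(self.joint_names), 3)
        roots = [i for i, p in enumerate(self.parent_index) if p is None]
        if len(roots) != 1:
            raise ValueError(f"hierarchy must have exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parent_index):
            if p is not None and not (0 <= p < i):
                raise ValueError(f"parent of joint {i} must precede it (got {p})")
        for order in self.channel_order:
            if sorted(order) != ["X", "Y", "Z"]:
                raise ValueError(f"channel order {order!r} is not a permutation of XYZ")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root_index(self) -> int:
        return self.parent_index.index(None)

    def children(self, j: int) -> list[int]:
        return [i for i, p in enumerate(self.parent_index) if p == j]


@dataclass
class MotionSequence:
    """Per-frame joint rotations.

    ``euler_frames`` is (F, J, 3) in degrees, each joint's angles in its
    declared channel order; ``quat_frames`` is (F, J, 4) scalar-first unit
    quaternions, absent until conversion.  Derived sequences (keyframe
    reconstructions) may carry quaternions only.
    """

    frame_time: float
    euler_frames: np.ndarray | None = None
    quat_frames: np.ndarray | None = None
    root_position: np.ndarray | None = None  # (F, 3) root translation, if captured

    def __post_init__(self):
        if self.frame_time <= 0:
            raise ValueError(f"frame_time must be positive, got {self.frame_time}")
        if self.euler_frames is None and self.quat_frames is None:
            raise ValueError("a MotionSequence needs euler_frames or quat_frames")
        if self.euler_frames is not None:
            self.euler_frames = np.asarray(self.euler_frames, dtype=float)
            if self.euler_frames.ndim != 3 or self.euler_frames.shape[2] != 3:
                raise ValueError("euler_frames must have shape (frames, joints, 3)")
        if self.quat_frames is not None:
            self.quat_frames = np.asarray(self.quat_frames, dtype=float)
            if self.quat_frames.ndim != 3 or self.quat_frames.shape[2] != 4:
                raise ValueError("quat_frames must have shape (frames, joints, 4)")
            norms = np.linalg.norm(self.quat_frames, axis=2)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("quat_frames must be unit quaternions (|q| = 1 within 1e-6)")
        if self.euler_frames is not None and self.quat_frames is not None:
            if self.euler_frames.shape[:2] != self.quat_frames.shape[:2]:
                raise ValueError("euler_frames and quat_frames disagree on frame/joint counts")
        if self.n_frames < 1:
            raise ValueError("a MotionSequence needs at least one frame")

    @property
    def n_frames(self) -> int:
        arr = self.euler_frames if self.euler_frames is not None else self.quat_frames
        return arr.shape[0]

    @property
    def n_joints(self) -> int:
        arr = self.euler_frames if self.euler_frames is not None else self.quat_frames
        return arr.shape[1]


#: Ordinal grade values live in :mod:`baduanjin.classify`; imported lazily in
#: MotionSample to avoid a cycle.
@dataclass
class MotionSample:
    """A labelled capture: one motion plus its class (1-8) and optional grade."""

    motion: MotionSequence
    motion_class: int
    subject_id: str = ""
    lesson: int | None = None
    grade: object | None = None  # an AccuracyGrade, when labelled

    def __post_init__(self):
        if self.motion_class not in range(1, 9):
            raise ValueError(f"motion_class must be 1..8, got {self.motion_class}")
        if self.lesson is not None and self.lesson < 1:
            raise ValueError("lesson must be >= 1")


# ---------------------------------------------------------------------------
# parsing


def _tokenize(text: str):
    """Yield (line_number, tokens) for each non-blank line."""
    for ln, raw in enumerate(text.splitlines(), start=1):
        toks = raw.replace("\t", " ").split()
        if toks:
            yield ln, toks


def parse_bvh(text: str) -> tuple[JointHierarchy, MotionSequence]:
    """Parse a BVH document into a hierarchy and a motion sequence.

    End sites are skipped (not treated as joints).  Translation channels
    are accepted on any joint; only the root's are retained, on
    ``MotionSequence.root_position``.  Raises :class:`BVHParseError` with
    the offending line number on malformed input.
    """
    lines = list(_tokenize(text))
    pos = 0

    def peek():
        return lines[pos] if pos < len(lines) else (None, None)

    def take():
        nonlocal pos
        if pos >= len(lines):
            raise BVHParseError("unexpected end of document")
        ln, toks = lines[pos]
        pos += 1
        return ln, toks

    ln, toks = take()
    if toks != ["HIERARCHY"]:
        raise BVHParseError("expected HIERARCHY", ln)

    names: list[str] = []
    parents: list[int | None] = []
    offsets: list[list[float]] = []
    orders: list[str] = []
    counts: list[int] = []
    channel_labels: list[list[str]] = []

    def parse_joint(parent: int | None):
        ln, toks = take()
        if toks[0] not in ("ROOT", "JOINT"):
            raise BVHParseError(f"expected ROOT or JOINT, got {toks[0]!r}", ln)
        if toks[0] == "ROOT" and parent is not None:
            raise BVHParseError("ROOT declared below the root", ln)
        if len(toks) < 2:
            raise BVHParseError("joint declaration lacks a name", ln)
        name = toks[1]
        me = len(names)
        names.append(name)
        parents.append(parent)
        offsets.append([0.0, 0.0, 0.0])
        orders.append("")
        counts.append(0)
        channel_labels.append([])

        ln, toks = take()
        if toks != ["{"]:
            raise BVHParseError("expected '{'", ln)
        while True:
            ln, toks = take()
            if toks == ["}"]:
                break
            if toks[0] == "OFFSET":
                if len(toks) != 4:
                    raise BVHParseError("OFFSET needs three values", ln)
                try:
                    offsets[me] = [float(v) for v in toks[1:4]]
                except ValueError:
                    raise BVHParseError("non-numeric OFFSET value", ln) from None
            elif toks[0] == "CHANNELS":
                try:
                    n = int(toks[1])
                except (IndexError, ValueError):
                    raise BVHParseError("CHANNELS needs a count", ln) from None
                labels = toks[2:]
                if len(labels) != n:
                    raise BVHParseError(f"CHANNELS declares {n} but lists {len(labels)}", ln)
                rot = [_ROT_LABEL[l] for l in labels if l in _ROT_LABEL]
                bad = [l for l in labels if l not in _ROT_LABEL and l not in _POS_LABELS]
                if bad:
                    raise BVHParseError(f"unknown channel label {bad[0]!r}", ln)
                if sorted(rot) != ["X", "Y", "Z"]:
                    raise BVHParseError("rotation channels must be a permutation of X/Y/Z", ln)
                orders[me] = "".join(rot)
                counts[me] = n
                channel_labels[me] = labels
            elif toks[0] == "End" or toks[0] == "End Site":
                # End Site block: skip its braces and offset
                ln2, t2 = take()
                if t2 != ["{"]:
                    raise BVHParseError("expected '{' after End Site", ln2)
                depth = 1
                while depth:
                    ln2, t2 = take()
                    if t2 == ["{"]:
                        depth += 1
                    elif t2 == ["}"]:
                        depth -= 1
            elif toks[0] == "JOINT":
                pos_back()
                parse_joint(me)
            else:
                raise BVHParseError(f"unexpected token {toks[0]!r} in joint block", ln)

    def pos_back():
        nonlocal pos
        pos -= 1

    parse_joint(None)

    for j, c in enumerate(counts):
        if c == 0:
            raise BVHParseError(f"joint {names[j]!r} declares no channels")

    ln, toks = take()
    if toks != ["MOTION"]:
        raise BVHParseError("expected MOTION", ln)
    ln, toks = take()
    # tolerate both "Frames: N" and "Frames : N"
    joined = " ".join(toks)
    if not joined.replace("Frames :", "Frames:").startswith("Frames:"):
        raise BVHParseError("expected Frames:", ln)
    try:
        n_frames = int(toks[-1])
    except ValueError:
        raise BVHParseError("non-integer frame count", ln) from None
    ln, toks = take()
    if toks[:2] != ["Frame", "Time:"]:
        raise BVHParseError("expected Frame Time:", ln)
    try:
        frame_time = float(toks[-1])
    except ValueError:
        raise BVHParseError("non-numeric frame time", ln) from None
    if frame_time <= 0:
        raise BVHParseError(f"frame time must be positive, got {frame_time}", ln)

    total_channels = sum(counts)
    J = len(names)
    euler = np.empty((n_frames, J, 3))
    root_pos = None
    root = parents.index(None)

    for f in range(n_frames):
        ln, toks = peek()
        if ln is None:
            raise BVHParseError(f"expected {n_frames} frame rows, found {f}")
        take()
        if len(toks) != total_channels:
            raise BVHParseError(
                f"frame row has {len(toks)} values, expected {total_channels}", ln
            )
        try:
            row = np.array([float(v) for v in toks])
        except ValueError:
            raise BVHParseError("non-numeric frame value", ln) from None
        col = 0
        for j in range(J):
            vals = row[col : col + counts[j]]
            col += counts[j]
            rot = [v for v, l in zip(vals, channel_labels[j]) if l in _ROT_LABEL]
            euler[f, j] = rot
            if j == root and counts[j] > 3:
                if root_pos is None:
                    root_pos = np.zeros((n_frames, 3))
                root_pos[f] = [v for v, l in zip(vals, channel_labels[j]) if l in _POS_LABELS]

    if pos < len(lines):
        ln, toks = peek()
        raise BVHParseError("trailing content after declared frames", ln)

    hierarchy = JointHierarchy(names, parents, np.array(offsets), orders, counts)
    motion = MotionSequence(frame_time=frame_time, euler_frames=euler, root_position=root_pos)
    return hierarchy, motion


# ---------------------------------------------------------------------------
# writing


def write_bvh(h: JointHierarchy, m: MotionSequence) -> str:
    """Serialize a hierarchy + motion back to BVH text.

    Angles are printed with 6 decimals, so ``parse_bvh(write_bvh(h, m))``
    reproduces the input within 1e-4 degrees.
    """
    if m.euler_frames is None:
        raise ValueError("write_bvh needs euler_frames (quaternion-only sequences cannot be written)")
    if m.n_joints != h.n_joints:
        raise ValueError(f"joint count mismatch: motion has {m.n_joints}, hierarchy {h.n_joints}")

    out = io.StringIO()
    out.write("HIERARCHY\n")

    def channels_line(j: int) -> str:
        rots = [f"{ax}rotation" for ax in h.channel_order[j]]
        if h.channel_counts[j] > 3:
            return "CHANNELS 6 Xposition Yposition Zposition " + " ".join(rots)
        return "CHANNELS 3 " + " ".join(rots)

    def emit(j: int, indent: int):
        pad = "  " * indent
        kw = "ROOT" if h.parent_index[j] is None else "JOINT"
        out.write(f"{pad}{kw} {h.joint_names[j]}\n{pad}{{\n")
        ox, oy, oz = h.offsets[j]
        out.write(f"{pad}  OFFSET {ox:.6f} {oy:.6f} {oz:.6f}\n")
        out.write(f"{pad}  {channels_line(j)}\n")
        kids = h.children(j)
        if kids:
            for c in kids:
                emit(c, indent + 1)
        else:
            out.write(f"{pad}  End Site\n{pad}  {{\n{pad}    OFFSET 0.000000 0.000000 0.000000\n{pad}  }}\n")
        out.write(f"{pad}}}\n")

    emit(h.root_index, 0)
    out.write("MOTION\n")
    out.write(f"Frames: {m.n_frames}\n")
    out.write(f"Frame Time: {m.frame_time:.7f}\n")

    root = h.root_index
    for f in range(m.n_frames):
        vals: list[float] = []
        for j in range(h.n_joints):
            if j == root and h.channel_counts[j] > 3:
                p = m.root_position[f] if m.root_position is not None else (0.0, 0.0, 0.0)
                vals.extend(p)
            vals.extend(m.euler_frames[f, j])
        out.write(" ".join(f"{v:.6f}" for v in vals) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# joint subsetting


def select_joints(
    h: JointHierarchy, m: MotionSequence, names=PERCEPTION_NEURON_17
) -> tuple[JointHierarchy, MotionSequence]:
    """Restrict a parsed file to a named joint profile, in profile order.

    Joints absent from the profile are dropped; kept joints are reparented
    to their nearest kept ancestor.  Raises if a profile name is missing
    from the file.
    """
    index = {n: i for i, n in enumerate(h.joint_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise ValueError(f"joints not present in file: {missing}")
    keep = [index[n] for n in names]
    # profile order must remain parent-before-child; sort by original DFS order
    keep.sort()
    kept_set = set(keep)
    new_index = {old: new for new, old in enumerate(keep)}

    def nearest_kept_ancestor(j: int) -> int | None:
        p = h.parent_index[j]
        while p is not None and p not in kept_set:
            p = h.parent_index[p]
        return p

    parents = []
    for old in keep:
        anc = nearest_kept_ancestor(old)
        parents.append(None if anc is None else new_index[anc])
    if parents.count(None) != 1:
        # subsetting removed the root's line to every kept joint; promote the first
        raise ValueError("joint profile must contain the root chain (exactly one root)")

    h2 = JointHierarchy(
        [h.joint_names[o] for o in keep],
        parents,
        h.offsets[keep],
        [h.channel_order[o] for o in keep],
        [h.channel_counts[o] if h.parent_index[o] is None else 3 for o in keep],
    )
    m2 = MotionSequence(
        frame_time=m.frame_time,
        euler_frames=m.euler_frames[:, keep, :] if m.euler_frames is not None else None,
        quat_frames=m.quat_frames[:, keep, :] if m.quat_frames is not None else None,
        root_position=m.root_position,
    )
    return h2, m2
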