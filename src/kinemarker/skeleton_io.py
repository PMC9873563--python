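"""Parsing, validation and basic kinematics for BVH full-body motion capture.

The wearable suit streams 17 inertially-sensed joints at 60 Hz and reports the
fused skeleton as a Biovision Hierarchy (BVH) text file: a joint tree with
per-joint Euler-angle channels followed by a frame-by-frame channel matrix.
This module parses those files into a validated in-memory model
(:class:`SkeletonModel` / :class:`MotionRecording`), runs forward kinematics to
recover world-frame 3D segment positions, differentiates joint angles into
angular velocities, and maps raw rotation channels onto anatomical labels
(flexion / abduction / rotation, dominant / non-dominant side).

Units are fixed package-wide: centimetres, degrees, seconds.

One deliberate dialect extension: a joint block may contain an ``End Site``
block *in addition to* child joints, so marker end sites can sit on internal
joints (sacrum, sternum, shoulder tips).  Ordinary BVH files, which only put a
single End Site in leaf joints, parse unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

__all__ = [
    "Joint",
    "EndSite",
    "SkeletonModel",
    "MotionRecording",
    "ChannelMapEntry",
    "ChannelMap",
    "KinematicsBundle",
    "BVHParseError",
    "parse_bvh",
    "write_bvh",
    "forward_kinematics",
    "compute_joint_velocities",
    "compute_kinematics",
    "anatomical_channel_map",
    "DEFAULT_JOINT_ALIASES",
]

TASKS = ("8MW", "9HPT-D", "9HPT-ND")
GROUPS = ("patient", "control")


class BVHParseError(ValueError):
    """Malformed BVH input; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Joint:
    """One node of the skeleton tree.

    ``parent`` is the index of the parent joint in skeleton order (``-1`` for
    the root), ``offset`` the rest-pose translation from the parent in cm, and
    ``rotation_order`` the CHANNELS rotation tokens verbatim, e.g. ``"ZXY"``.
    """

    name: str
    parent: int
    offset: tuple[float, float, float]
    rotation_order: str
    has_translation: bool = False


@dataclass(frozen=True)
class EndSite:
    """Terminal marker offset attached to ``parent`` (a joint index)."""

    parent: int
    offset: tuple[float, float, float]
    name: str = "End Site"


@dataclass(frozen=True)
class SkeletonModel:
    """Joint hierarchy of a recording.

    Invariants enforced at construction: exactly one root whose parent index
    is ``-1``; every non-root joint's parent precedes it in order; each joint
    carries exactly 3 rotation channels (the root may add 3 translations).
    """

    joints: tuple[Joint, ...]
    end_sites: tuple[EndSite, ...] = ()

    # The study suit: 3 DoF x 17 joints = 51 angular channels and
    # 17 joints + 9 end sites = 26 tracked segments (78 position DoF).
    SUIT_N_ROTATION_CHANNELS = 51
    SUIT_N_SEGMENTS = 26

    def __post_init__(self):
        if not self.joints:
            raise ValueError("skeleton has no joints")
        roots = [i for i, j in enumerate(self.joints) if j.parent == -1]
        if roots != [0]:
            raise ValueError("skeleton must have exactly one root joint, first in order")
        for i, j in enumerate(self.joints[1:], start=1):
            if not 0 <= j.parent < i:
                raise ValueError(f"joint {j.name!r}: parent index must precede the joint")
            if j.has_translation:
                raise ValueError(f"joint {j.name!r}: only the root may carry translations")
        for j in self.joints:
            if sorted(j.rotation_order) != ["X", "Y", "Z"]:
                raise ValueError(f"joint {j.name!r}: rotation order must permute XYZ, got {j.rotation_order!r}")
        for e in self.end_sites:
            if not 0 <= e.parent < len(self.joints):
                raise ValueError("end site parent index out of range")

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def n_rotation_channels(self) -> int:
        return 3 * len(self.joints)

    @property
    def n_segments(self) -> int:
        return len(self.joints) + len(self.end_sites)

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(j.name for j in self.joints)

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"no joint named {name!r}") from None

    def channel_names(self) -> list[str]:
        """Rotation-channel labels in file order, e.g. ``"LeftHip:Xrotation"``."""
        out = []
        for j in self.joints:
            for ax in j.rotation_order:
                out.append(f"{j.name}:{ax}rotation")
        return out

    def segment_names(self) -> list[str]:
        names = [j.name for j in self.joints]
        for e in self.end_sites:
            names.append(f"{self.joints[e.parent].name}:{e.name}")
        return names


@dataclass
class MotionRecording:
    """A parsed motion file plus study metadata.

    ``angles`` is frames x (3 * n_joints) Euler angles in degrees, columns in
    skeleton channel order; ``root_translation`` is frames x 3 in cm.
    """

    skeleton: SkeletonModel
    angles: np.ndarray
    root_translation: np.ndarray
    frame_rate: float = 60.0
    subject_id: str = ""
    visit_id: str = ""
    task: str = "8MW"
    group: str = "patient"
    hand_dominance: str = "right"

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.root_translation = np.asarray(self.root_translation, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.angles.ndim != 2 or self.angles.shape[0] < 2:
            raise ValueError("recording needs at least 2 frames")
        if self.angles.shape[1] != self.skeleton.n_rotation_channels:
            raise ValueError(
                f"angle columns ({self.angles.shape[1]}) do not match skeleton "
                f"rotation channels ({self.skeleton.n_rotation_channels})"
            )
        if self.root_translation.shape != (self.angles.shape[0], 3):
            raise ValueError("root_translation must be frames x 3")
        if not np.all(np.isfinite(self.angles)) or not np.all(np.isfinite(self.root_translation)):
            raise ValueError("non-finite values in motion data")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class ChannelMapEntry:
    joint: str
    axis_label: str  # flexion | abduction | rotation
    side: str  # dominant | nondominant | midline
    region: str  # lower | upper | head/spine


@dataclass(frozen=True)
class ChannelMap:
    """Anatomical labelling of every rotation channel of a skeleton."""

    entries: tuple[ChannelMapEntry, ...]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.entries) != len(self.channel_names):
            raise ValueError("one entry per channel required")

    def __len__(self) -> int:
        return len(self.entries)

    def select(self, *, region=None, side=None, axis_label=None, joints=None) -> np.ndarray:
        """Channel indices matching all given filters (each may be a str or set)."""

        def _match(value, crit):
            if crit is None:
                return True
            if isinstance(crit, str):
                return value == crit
            return value in crit

        idx = [
            i
            for i, e in enumerate(self.entries)
            if _match(e.region, region) and _match(e.side, side)
            and _match(e.axis_label, axis_label) and _match(e.joint, joints)
        ]
        return np.asarray(idx, dtype=int)

    def find(self, joint: str, axis_label: str) -> int:
        for i, e in enumerate(self.entries):
            if e.joint == joint and e.axis_label == axis_label:
                return i
        raise KeyError(f"no channel {joint}/{axis_label}")


@dataclass
class KinematicsBundle:
    """Derived kinematics of one recording.

    ``segment_positions`` are world-frame cm; ``hip_frame_positions`` are the
    same positions re-expressed with the pelvis (root) pinned at the origin,
    i.e. the trunk-referenced frame used by the workspace and head-sway
    features.  ``angular_velocity`` is deg/s, one row per frame.
    """

    recording: MotionRecording
    angular_velocity: np.ndarray | None = None
    segment_positions: np.ndarray | None = None
    hip_frame_positions: np.ndarray | None = None
    channel_map: ChannelMap | None = None

    @property
    def frame_rate(self) -> float:
        return self.recording.frame_rate


# ---------------------------------------------------------------------------
# BVH parsing / writing
# ---------------------------------------------------------------------------

_ROT_TOKENS = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}
_POS_TOKENS = {"Xposition", "Yposition", "Zposition"}


class _Lines:
    def __init__(self, text: str):
        self.raw = text.splitlines()
        self.pos = 0

    def next(self) -> tuple[int, str]:
        while self.pos < len(self.raw):
            line = self.raw[self.pos].strip()
            self.pos += 1
            if line:
                return self.pos, line
        raise BVHParseError("unexpected end of file", len(self.raw))

    def peek(self) -> tuple[int, str]:
        save = self.pos
        try:
            return self.next()
        finally:
            self.pos = save


def _parse_offset(line: str, n: int) -> tuple[float, float, float]:
    parts = line.split()
    if parts[0] != "OFFSET" or len(parts) != 4:
        raise BVHParseError(f"expected OFFSET x y z, got {line!r}", n)
    try:
        return tuple(float(v) for v in parts[1:])  # type: ignore[return-value]
    except ValueError:
        raise BVHParseError(f"non-numeric OFFSET in {line!r}", n) from None


def _parse_joint_block(lines: _Lines, name: str, parent: int, joints: list[Joint],
                       ends: list[EndSite], channel_layout: list[tuple[int, str]]):
    n, line = lines.next()
    if line != "{":
        raise BVHParseError(f"expected '{{' after joint {name!r}", n)
    n, line = lines.next()
    offset = _parse_offset(line, n)
    n, line = lines.next()
    parts = line.split()
    if parts[0] != "CHANNELS":
        raise BVHParseError(f"expected CHANNELS for joint {name!r}", n)
    try:
        count = int(parts[1])
    except (IndexError, ValueError):
        raise BVHParseError("CHANNELS needs an integer count", n) from None
    tokens = parts[2:]
    if len(tokens) != count:
        raise BVHParseError(f"CHANNELS count {count} does not match {len(tokens)} tokens", n)
    rot = [t for t in tokens if t in _ROT_TOKENS]
    trans = [t for t in tokens if t in _POS_TOKENS]
    if len(rot) + len(trans) != count:
        bad = next(t for t in tokens if t not in _ROT_TOKENS and t not in _POS_TOKENS)
        raise BVHParseError(f"unknown channel token {bad!r}", n)
    if len(rot) != 3:
        raise BVHParseError(f"joint {name!r} must have exactly 3 rotation channels", n)
    if trans and parent != -1:
        raise BVHParseError(f"non-root joint {name!r} carries translation channels", n)
    index = len(joints)
    joints.append(Joint(name=name, parent=parent,
                        offset=offset, rotation_order="".join(_ROT_TOKENS[t] for t in rot),
                        has_translation=bool(trans)))
    # record file-order channel layout for this joint
    for t in tokens:
        channel_layout.append((index, t))
    while True:
        n, line = lines.next()
        if line == "}":
            return
        parts = line.split()
        if parts[0] == "JOINT":
            if len(parts) < 2:
                raise BVHParseError("JOINT without a name", n)
            _parse_joint_block(lines, " ".join(parts[1:]), index, joints, ends, channel_layout)
        elif parts[0] == "End" and len(parts) >= 2 and parts[1] == "Site":
            n, line = lines.next()
            if line != "{":
                raise BVHParseError("expected '{' after End Site", n)
            n, line = lines.next()
            ends.append(EndSite(parent=index, offset=_parse_offset(line, n)))
            n, line = lines.next()
            if line != "}":
                raise BVHParseError("expected '}' closing End Site", n)
        else:
            raise BVHParseError(f"unexpected token inside joint {name!r}: {line!r}", n)


def parse_bvh(path_or_buffer, **metadata) -> MotionRecording:
    """Parse a BVH file into a :class:`MotionRecording`.

    Parameters
    ----------
    path_or_buffer : str, Path or file-like
        BVH text source (HIERARCHY + MOTION sections).
    **metadata
        Optional study metadata forwarded to the recording
        (``subject_id``, ``visit_id``, ``task``, ``group``, ``hand_dominance``).

    Raises
    ------
    BVHParseError
        On malformed hierarchy, header/frame channel-count mismatch or
        non-numeric frame data, naming the offending line.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = _Lines(text)
    n, line = lines.next()
    if line != "HIERARCHY":
        raise BVHParseError(f"expected HIERARCHY, got {line!r}", n)
    n, line = lines.next()
    parts = line.split()
    if parts[0] != "ROOT" or len(parts) < 2:
        raise BVHParseError(f"expected ROOT <name>, got {line!r}", n)
    joints: list[Joint] = []
    ends: list[EndSite] = []
    layout: list[tuple[int, str]] = []
    _parse_joint_block(lines, " ".join(parts[1:]), -1, joints, ends, layout)
    skeleton = SkeletonModel(joints=tuple(joints), end_sites=tuple(ends))

    n, line = lines.next()
    if line != "MOTION":
        raise BVHParseError(f"expected MOTION, got {line!r}", n)
    n, line = lines.next()
    if not line.startswith("Frames:"):
        raise BVHParseError(f"expected 'Frames:', got {line!r}", n)
    try:
        n_frames = int(line.split(":", 1)[1])
    except ValueError:
        raise BVHParseError("non-integer frame count", n) from None
    n, line = lines.next()
    if not line.lower().startswith("frame time:"):
        raise BVHParseError(f"expected 'Frame Time:', got {line!r}", n)
    try:
        frame_time = float(line.split(":", 1)[1])
    except ValueError:
        raise BVHParseError("non-numeric frame time", n) from None
    if frame_time <= 0:
        raise BVHParseError("Frame Time must be positive", n)

    n_channels = len(layout)
    data = np.empty((n_frames, n_channels), dtype=float)
    for i in range(n_frames):
        n, line = lines.next()
        vals = line.split()
        if len(vals) != n_channels:
            raise BVHParseError(
                f"frame row has {len(vals)} values for a {n_channels}-channel header", n)
        try:
            data[i] = [float(v) for v in vals]
        except ValueError:
            raise BVHParseError("non-numeric frame data", n) from None
    if not np.all(np.isfinite(data)):
        raise BVHParseError("non-finite frame data")

    # split file-order channels into root translation + per-joint rotations
    trans = np.zeros((n_frames, 3), dtype=float)
    angles = np.empty((n_frames, skeleton.n_rotation_channels), dtype=float)
    rot_cursor = {}
    for col, (jidx, token) in enumerate(layout):
        if token in _POS_TOKENS:
            trans[:, "XYZ".index(token[0])] = data[:, col]
        else:
            k = rot_cursor.get(jidx, 0)
            angles[:, 3 * jidx + k] = data[:, col]
            rot_cursor[jidx] = k + 1
    return MotionRecording(skeleton=skeleton, angles=angles, root_translation=trans,
                           frame_rate=1.0 / frame_time, **metadata)


def write_bvh(recording: MotionRecording, path) -> None:
    """Serialize a recording as BVH text (6-decimal floats, FrameTime = 1/rate)."""
    if recording.n_frames < 1:
        raise ValueError("refusing to write a recording with no frames")
    sk = recording.skeleton
    children: dict[int, list[int]] = {i: [] for i in range(-1, sk.n_joints)}
    for i, j in enumerate(sk.joints):
        children[j.parent].append(i)
    ends_by_parent: dict[int, list[EndSite]] = {}
    for e in sk.end_sites:
        ends_by_parent.setdefault(e.parent, []).append(e)

    buf = io.StringIO()
    buf.write("HIERARCHY\n")

    def fmt(v: float) -> str:
        return f"{v:.6f}"

    def emit(idx: int, depth: int):
        j = sk.joints[idx]
        pad = "  " * depth
        kw = "ROOT" if j.parent == -1 else "JOINT"
        buf.write(f"{pad}{kw} {j.name}\n{pad}{{\n")
        pad2 = "  " * (depth + 1)
        buf.write(f"{pad2}OFFSET {' '.join(fmt(v) for v in j.offset)}\n")
        rot_tokens = " ".join(f"{ax}rotation" for ax in j.rotation_order)
        if j.parent == -1:
            buf.write(f"{pad2}CHANNELS 6 Xposition Yposition Zposition {rot_tokens}\n")
        else:
            buf.write(f"{pad2}CHANNELS 3 {rot_tokens}\n")
        for e in ends_by_parent.get(idx, []):
            buf.write(f"{pad2}End Site\n{pad2}{{\n")
            buf.write(f"{pad2}  OFFSET {' '.join(fmt(v) for v in e.offset)}\n")
            buf.write(f"{pad2}}}\n")
        for c in children[idx]:
            emit(c, depth + 1)
        buf.write(f"{pad}}}\n")

    emit(0, 0)
    buf.write("MOTION\n")
    buf.write(f"Frames: {recording.n_frames}\n")
    buf.write(f"Frame Time: {1.0 / recording.frame_rate:.7f}\n")
    for f in range(recording.n_frames):
        row = list(recording.root_translation[f]) + list(recording.angles[f])
        buf.write(" ".join(fmt(v) for v in row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(recording: MotionRecording, remove_root_yaw: bool = False) -> KinematicsBundle:
    """World-frame segment positions by recursive offset + rotation composition.

    Each joint's local rotation is built from its Euler channels in the order
    stated on its CHANNELS line (intrinsic composition, BVH convention) and
    chained down the tree; end sites are rigid offsets in their parent's frame.
    ``hip_frame_positions`` subtract the root position frame-wise (and, if
    ``remove_root_yaw``, undo the root's rotation about the vertical axis), so
    the pelvis is pinned at the origin — the trunk-referenced frame used by the
    workspace features.
    """
    sk = recording.skeleton
    F = recording.n_frames
    local = []
    for i, j in enumerate(sk.joints):
        eul = recording.angles[:, 3 * i: 3 * i + 3]
        local.append(Rotation.from_euler(j.rotation_order, eul, degrees=True))
    world_rot: list[Rotation] = [None] * sk.n_joints  # type: ignore[list-item]
    pos = np.empty((F, sk.n_segments, 3), dtype=float)
    for i, j in enumerate(sk.joints):
        off = np.asarray(j.offset)
        if j.parent == -1:
            world_rot[i] = local[i]
            pos[:, i] = off + recording.root_translation
        else:
            pr = world_rot[j.parent]
            world_rot[i] = pr * local[i]
            pos[:, i] = pos[:, j.parent] + pr.apply(off)
    for k, e in enumerate(sk.end_sites):
        pos[:, sk.n_joints + k] = pos[:, e.parent] + world_rot[e.parent].apply(np.asarray(e.offset))

    hip = pos - pos[:, [0]]
    if remove_root_yaw:
        # yaw = rotation of the root about the vertical (Y) axis
        fwd = world_rot[0].apply(np.array([0.0, 0.0, 1.0]))
        yaw = np.arctan2(fwd[:, 0], fwd[:, 2])
        c, s = np.cos(-yaw), np.sin(-yaw)
        x, z = hip[..., 0], hip[..., 2]
        hip = hip.copy()
        hip[..., 0] = c[:, None] * x + s[:, None] * z
        hip[..., 2] = -s[:, None] * x + c[:, None] * z
    return KinematicsBundle(recording=recording, segment_positions=pos, hip_frame_positions=hip)


def compute_joint_velocities(recording: MotionRecording, lowpass_hz: float | None = None) -> np.ndarray:
    """Per-channel angular velocity in deg/s.

    Angles are unwrapped modulo 360 deg per channel, differentiated by central
    differences (one-sided at the ends), and optionally low-pass filtered with
    a 4th-order zero-phase Butterworth at ``lowpass_hz``.
    """
    if recording.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    fr = recording.frame_rate
    if lowpass_hz is not None and lowpass_hz >= fr / 2:
        raise ValueError(f"lowpass_hz={lowpass_hz} must be below the Nyquist frequency {fr / 2}")
    ang = np.unwrap(recording.angles, axis=0, period=360.0)
    vel = np.gradient(ang, 1.0 / fr, axis=0)
    if lowpass_hz is not None:
        b, a = butter(4, lowpass_hz / (fr / 2))
        vel = filtfilt(b, a, vel, axis=0)
    return vel


def compute_kinematics(recording: MotionRecording, lowpass_hz: float | None = None,
                       remove_root_yaw: bool = False,
                       joint_aliases: dict[str, str] | None = None) -> KinematicsBundle:
    """Full bundle: forward kinematics + angular velocities + channel map."""
    bundle = forward_kinematics(recording, remove_root_yaw=remove_root_yaw)
    bundle.angular_velocity = compute_joint_velocities(recording, lowpass_hz=lowpass_hz)
    bundle.channel_map = anatomical_channel_map(
        recording.skeleton, recording.hand_dominance, joint_aliases=joint_aliases)
    return bundle


# ---------------------------------------------------------------------------
# Anatomical channel mapping
# ---------------------------------------------------------------------------

# canonical joint name -> (side_group, region); side_group in {left, right, midline}
_CANONICAL_ANATOMY = {
    "Hips": ("midline", "lower"),
    "Spine": ("midline", "head/spine"),
    "Chest": ("midline", "head/spine"),
    "Neck": ("midline", "head/spine"),
    "Head": ("midline", "head/spine"),
    "LeftShoulder": ("left", "upper"),
    "LeftElbow": ("left", "upper"),
    "LeftWrist": ("left", "upper"),
    "RightShoulder": ("right", "upper"),
    "RightElbow": ("right", "upper"),
    "RightWrist": ("right", "upper"),
    "LeftHip": ("left", "lower"),
    "LeftKnee": ("left", "lower"),
    "LeftAnkle": ("left", "lower"),
    "RightHip": ("right", "lower"),
    "RightKnee": ("right", "lower"),
    "RightAnkle": ("right", "lower"),
}

# Aliases for other vendors' naming conventions; extendable via config.
DEFAULT_JOINT_ALIASES: dict[str, str] = {
    "LeftUpLeg": "LeftHip", "RightUpLeg": "RightHip",
    "LeftLeg": "LeftKnee", "RightLeg": "RightKnee",
    "LeftFoot": "LeftAnkle", "RightFoot": "RightAnkle",
    "LeftArm": "LeftShoulder", "RightArm": "RightShoulder",
    "LeftForeArm": "LeftElbow", "RightForeArm": "RightElbow",
    "LeftHand": "LeftWrist", "RightHand": "RightWrist",
    "Spine1": "Chest", "Chest2": "Chest", "Torso": "Chest",
}

# rotation axis -> anatomical movement dimension (suit convention: X sagittal,
# Z frontal, Y transverse)
_AXIS_LABEL = {"X": "flexion", "Z": "abduction", "Y": "rotation"}


def anatomical_channel_map(skeleton: SkeletonModel, hand_dominance: str = "right",
                           joint_aliases: dict[str, str] | None = None) -> ChannelMap:
    """Label every rotation channel anatomically.

    The dominant side is the writing hand: for a right-handed subject all
    ``Right*`` channels are labelled ``dominant`` and ``Left*`` channels
    ``nondominant`` (and vice versa).  Unknown joint names are resolved through
    the alias table; an unmapped name raises a ``KeyError`` listing it.
    """
    if hand_dominance not in ("left", "right"):
        raise ValueError("hand_dominance must be 'left' or 'right'")
    aliases = dict(DEFAULT_JOINT_ALIASES)
    if joint_aliases:
        aliases.update(joint_aliases)
    entries = []
    names = []
    for j in skeleton.joints:
        canonical = aliases.get(j.name, j.name)
        if canonical not in _CANONICAL_ANATOMY:
            raise KeyError(
                f"joint {j.name!r} is not in the anatomical table and has no alias; "
                "extend the alias table in the run config")
        side_group, region = _CANONICAL_ANATOMY[canonical]
        if side_group == "midline":
            side = "midline"
        else:
            side = "dominant" if side_group == hand_dominance else "nondominant"
        for ax in j.rotation_order:
            entries.append(ChannelMapEntry(joint=canonical, axis_label=_AXIS_LABEL[ax],
                                           side=side, region=region))
            names.append(f"{j.name}:{ax}rotation")
    required = {"Head"}
    present = {e.joint for e in entries}
    missing = required - present
    if missing:
        raise KeyError(f"skeleton is missing required joints: {sorted(missing)}")
    return ChannelMap(entries=tuple(entries), channel_names=tuple(names))
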