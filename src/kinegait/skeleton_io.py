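"""Reading, writing and validation of skeletal walking trials.

A trial is a time-stamped sequence of 32-joint skeletons as produced by a
depth-camera body tracker (Azure-Kinect-style joint set). Files are plain
JSON, one object per trial::

    {
      "schema_version": 1,
      "subject_id": "S01", "trial_id": 1, "group": "HC",
      "frames": [
        {"t": 0.0, "joints": {"PELVIS": {"p": [x, y, z], "c": 0.95}, ...}},
        ...
      ]
    }

Positions are in millimetres in the camera frame with the package-wide
coordinate convention: x mediolateral (positive toward the subject's left),
y vertical (positive up), z distance from the camera (positive away, so z
decreases as the subject walks toward the sensor). Trackers that emit a
y-down depth frame must be normalized to y-up on export; the simulator and
all analysis code assume y-up. The per-joint confidence score ``c`` in
[0, 1] is optional, stored when present, and never used to gate analysis.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SchemaError, TrialParseError, UnknownJointError

SCHEMA_VERSION = 1


class JointId(str, enum.Enum):
    """The 32 joints of the tracked skeleton."""

    PELVIS = "PELVIS"
    SPINE_NAVEL = "SPINE_NAVEL"
    SPINE_CHEST = "SPINE_CHEST"
    NECK = "NECK"
    CLAVICLE_L = "CLAVICLE_L"
    SHOULDER_L = "SHOULDER_L"
    ELBOW_L = "ELBOW_L"
    WRIST_L = "WRIST_L"
    HAND_L = "HAND_L"
    HANDTIP_L = "HANDTIP_L"
    THUMB_L = "THUMB_L"
    CLAVICLE_R = "CLAVICLE_R"
    SHOULDER_R = "SHOULDER_R"
    ELBOW_R = "ELBOW_R"
    WRIST_R = "WRIST_R"
    HAND_R = "HAND_R"
    HANDTIP_R = "HANDTIP_R"
    THUMB_R = "THUMB_R"
    HIP_L = "HIP_L"
    KNEE_L = "KNEE_L"
    ANKLE_L = "ANKLE_L"
    FOOT_L = "FOOT_L"
    HIP_R = "HIP_R"
    KNEE_R = "KNEE_R"
    ANKLE_R = "ANKLE_R"
    FOOT_R = "FOOT_R"
    HEAD = "HEAD"
    NOSE = "NOSE"
    EYE_L = "EYE_L"
    EAR_L = "EAR_L"
    EYE_R = "EYE_R"
    EAR_R = "EAR_R"


JOINT_NAMES: tuple[str, ...] = tuple(j.value for j in JointId)
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

#: Joints the analysis pipeline actually consumes; a trial missing any of
#: these is rejected at read time.
REQUIRED_JOINTS: tuple[str, ...] = (
    "PELVIS",
    "HIP_L",
    "HIP_R",
    "ANKLE_L",
    "ANKLE_R",
    "SHOULDER_L",
    "SHOULDER_R",
    "WRIST_L",
    "WRIST_R",
)


def _as_joint_index(joint: "JointId | str") -> int:
    name = joint.value if isinstance(joint, JointId) else str(joint)
    try:
        return JOINT_INDEX[name]
    except KeyError:
        raise UnknownJointError(f"unknown joint name: {name!r}") from None


@dataclass
class SkeletonSequence:
    """One walking trial: timestamps plus 32-joint 3D positions.

    Parameters
    ----------
    times
        Shape ``(n,)`` timestamps in seconds, strictly increasing.
    positions
        Shape ``(n, 32, 3)`` joint positions in millimetres, joint axis
        ordered as :data:`JOINT_NAMES`.
    confidence
        Optional ``(n, 32)`` per-joint tracking confidence in [0, 1].
    """

    times: np.ndarray
    positions: np.ndarray
    confidence: np.ndarray | None = None
    subject_id: str = ""
    trial_id: int = 0
    group: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise SchemaError("a trial needs at least 2 frames")
        n = self.times.size
        if self.positions.shape != (n, len(JOINT_NAMES), 3):
            raise SchemaError(
                f"positions must have shape ({n}, 32, 3), "
                f"got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.times)):
            raise DataError("non-finite timestamp")
        if not np.all(np.diff(self.times) > 0):
            raise DataError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise DataError("non-finite joint coordinate")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (n, len(JOINT_NAMES)):
                raise SchemaError("confidence must have shape (n_frames, 32)")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def joint(self, joint: "JointId | str") -> np.ndarray:
        """Positions of one joint, shape ``(n, 3)`` millimetres."""
        return self.positions[:, _as_joint_index(joint), :]


def joint_trajectory(
    seq: SkeletonSequence, joint: "JointId | str"
) -> tuple[np.ndarray, np.ndarray]:
    """Timestamps and 3D positions of one named joint.

    Returns ``(times, xyz)`` with ``xyz`` of shape ``(n, 3)`` in
    millimetres, order preserved from the trial.
    """
    return seq.times.copy(), seq.joint(joint).copy()


def read_trial(path) -> SkeletonSequence:
    """Read and validate a trial JSON file.

    Raises
    ------
    TrialParseError
        If the file is not valid JSON.
    SchemaError
        If a frame is malformed or a required joint is missing (the
        message names the missing joint).
    DataError
        If timestamps are not strictly increasing or a coordinate is
        non-finite.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise TrialParseError(f"{path}: malformed JSON: {e}") from e
    if not isinstance(doc, dict) or "frames" not in doc:
        raise SchemaError(f"{path}: missing 'frames' array")
    frames = doc["frames"]
    if not isinstance(frames, list) or len(frames) < 2:
        raise SchemaError(f"{path}: a trial needs at least 2 frames")

    n = len(frames)
    times = np.empty(n)
    positions = np.empty((n, len(JOINT_NAMES), 3))
    has_conf = all(
        "c" in j for f in frames for j in f.get("joints", {}).values()
    )
    confidence = np.empty((n, len(JOINT_NAMES))) if has_conf else None

    for i, frame in enumerate(frames):
        if "t" not in frame or "joints" not in frame:
            raise SchemaError(f"{path}: frame {i} missing 't' or 'joints'")
        times[i] = float(frame["t"])
        joints = frame["joints"]
        for name in REQUIRED_JOINTS:
            if name not in joints:
                raise SchemaError(
                    f"{path}: frame {i} missing required joint {name!r}"
                )
        for name, idx in JOINT_INDEX.items():
            if name not in joints:
                raise SchemaError(f"{path}: frame {i} missing joint {name!r}")
            entry = joints[name]
            p = entry.get("p")
            if p is None or len(p) != 3:
                raise SchemaError(
                    f"{path}: frame {i} joint {name!r} needs a 3-vector 'p'"
                )
            positions[i, idx] = p
            if has_conf:
                confidence[i, idx] = float(entry["c"])

    return SkeletonSequence(
        times=times,
        positions=positions,
        confidence=confidence,
        subject_id=str(doc.get("subject_id", "")),
        trial_id=int(doc.get("trial_id", 0)),
        group=str(doc.get("group", "")),
    )


def write_trial(seq: SkeletonSequence, path) -> None:
    """Write a trial so that :func:`read_trial` restores it bit-exactly.

    Floats are serialized with ``repr`` (Python's shortest round-trip
    representation), so timestamps and positions survive a write/read
    cycle without loss. The confidence field is omitted entirely when the
    sequence carries none.
    """
    frames = []
    for i in range(seq.n_frames):
        joints = {}
        for name, idx in JOINT_INDEX.items():
            entry = {"p": [float(v) for v in seq.positions[i, idx]]}
            if seq.confidence is not None:
                entry["c"] = float(seq.confidence[i, idx])
            joints[name] = entry
        frames.append({"t": float(seq.times[i]), "joints": joints})
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": seq.subject_id,
        "trial_id": seq.trial_id,
        "group": seq.group,
        "frames": frames,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


_MIRROR_MAP: dict[int, int] = {}
for _name, _idx in JOINT_INDEX.items():
    if _name.endswith("_L"):
        _MIRROR_MAP[_idx] = JOINT_INDEX[_name[:-2] + "_R"]
    elif _name.endswith("_R"):
        _MIRROR_MAP[_idx] = JOINT_INDEX[_name[:-2] + "_L"]
    else:
        _MIRROR_MAP[_idx] = _idx


def mirror_x(seq: SkeletonSequence) -> SkeletonSequence:
    """Mirror a trial about the sagittal plane: negate x, swap L/R joints.

    Used by symmetry tests: a mirrored trial must yield identical
    asymmetry indices and synchrony magnitudes with side labels swapped.
    """
    perm = np.array([_MIRROR_MAP[i] for i in range(len(JOINT_NAMES))])
    pos = seq.positions[:, perm, :].copy()
    pos[:, :, 0] = -pos[:, :, 0]
    conf = None if seq.confidence is None else seq.confidence[:, perm].copy()
    return SkeletonSequence(
        times=seq.times.copy(),
        positions=pos,
        confidence=conf,
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
        group=seq.group,
    )
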