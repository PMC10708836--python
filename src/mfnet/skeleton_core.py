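"""Skeleton data model, sequence I/O, temporal resampling and manifests.

A sample is a sequence of 3D poses: ``coords`` shaped (T, N, 3) with N = 20
joints, the layout used by depth-sensor capture of full-body motion.  Joint
numbering follows the 1-based convention of the part equations (five parts:
left/right arm, left/right leg, trunk, each a center joint plus three member
joints); internally arrays are 0-based and :class:`JointIndexMap` carries the
fixed mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_JOINTS = 20

#: part -> (center joint, member joints), 1-based, in the canonical order
#: (members listed in the order their difference vectors are concatenated)
PART_DEFS = {
    "LA": (7, (8, 19, 9)),
    "RA": (4, (5, 17, 6)),
    "LL": (13, (14, 20, 15)),
    "RL": (10, (11, 18, 12)),
    "TRUNK": (1, (2, 3, 16)),
}
PART_ORDER = ("LA", "RA", "LL", "RL", "TRUNK")


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


@dataclass(frozen=True)
class JointIndexMap:
    """1-based joint numbering -> 0-based rows, plus part membership.

    ``hand_joints`` designates the (left, right) hand joints; the default
    picks the terminal member of each arm chain (left 9, right 6).
    """

    part_membership: dict = field(
        default_factory=lambda: dict(PART_DEFS))
    hand_joints: tuple = (9, 6)
    n_joints: int = N_JOINTS

    def __post_init__(self):
        for part, (center, members) in self.part_membership.items():
            if len(set(members)) != len(members):
                raise ValidationError(
                    f"duplicate member joint in part {part!r}")
            for j in (center, *members):
                if not 1 <= j <= self.n_joints:
                    raise ValidationError(
                        f"joint {j} of part {part!r} outside 1..{self.n_joints}")

    def idx(self, joint_number: int) -> int:
        """0-based array row of a 1-based joint number."""
        if not 1 <= joint_number <= self.n_joints:
            raise ValidationError(
                f"joint number {joint_number} outside 1..{self.n_joints}")
        return joint_number - 1


DEFAULT_JOINT_MAP = JointIndexMap()


@dataclass
class SkeletonSequence:
    """One labeled motion sample: (T, n_joints, 3) coordinates."""

    coords: np.ndarray
    label: int | None = None
    sample_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must be (T, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise ValidationError(
                "sequence needs at least 3 frames (acceleration is a second "
                f"difference), got {self.coords.shape[0]}")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]


@dataclass
class ManifestEntry:
    path: str
    label: int
    sample_id: str


@dataclass
class DatasetManifest:
    entries: list
    class_names: list
    n_classes: int

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValidationError("n_classes must be >= 1")
        for e in self.entries:
            if not 0 <= e.label < self.n_classes:
                raise ValidationError(
                    f"entry {e.sample_id!r}: label {e.label} outside "
                    f"[0, {self.n_classes})")

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=int)


def load_manifest(path) -> DatasetManifest:
    """Read a JSON manifest; relative entry paths resolve against its folder."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    entries = []
    for e in raw["entries"]:
        p = Path(e["path"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise FileNotFoundError(
                f"manifest entry {e.get('sample_id')!r}: missing file {p}")
        entries.append(ManifestEntry(str(p), int(e["label"]),
                                     str(e.get("sample_id", p.stem))))
    return DatasetManifest(entries=entries,
                           class_names=list(raw["class_names"]),
                           n_classes=int(raw["n_classes"]))


def save_manifest(manifest: DatasetManifest, path) -> None:
    payload = {
        "n_classes": manifest.n_classes,
        "class_names": manifest.class_names,
        "entries": [{"path": e.path, "label": int(e.label),
                     "sample_id": e.sample_id} for e in manifest.entries],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _csv_header(n_joints: int) -> list:
    return [f"j{j:02d}_{ax}" for j in range(1, n_joints + 1)
            for ax in ("x", "y", "z")]


def load_sequence(path, expected_joints: int = N_JOINTS) -> SkeletonSequence:
    """Load one sequence from CSV (T rows x 3N columns) or an ``.npz`` container."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            coords = np.asarray(data["coords"], dtype=np.float64)
            label = int(data["label"]) if "label" in data else None
    else:
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if table.shape[1] != 3 * expected_joints:
            raise ValidationError(
                f"{path.name}: expected {3 * expected_joints} columns, "
                f"got {table.shape[1]}")
        coords = table.reshape(table.shape[0], expected_joints, 3)
        label = None
    if coords.shape[1] != expected_joints:
        raise ValidationError(
            f"{path.name}: expected {expected_joints} joints, "
            f"got {coords.shape[1]}")
    return SkeletonSequence(coords=coords, label=label, sample_id=path.stem)


def save_sequence(seq: SkeletonSequence, path) -> None:
    """Write a sequence as CSV or ``.npz`` depending on the file suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        payload = {"coords": seq.coords}
        if seq.label is not None:
            payload["label"] = np.int64(seq.label)
        np.savez(path, **payload)
    else:
        flat = seq.coords.reshape(seq.n_frames, -1)
        header = ",".join(_csv_header(seq.n_joints))
        np.savetxt(path, flat, delimiter=",", header=header, comments="")


def interpolate_to_length(x: np.ndarray, length: int) -> np.ndarray:
    """Linearly resample rows of ``x`` (T, ...) onto a uniform grid of ``length``.

    Endpoints are preserved exactly; ``length == T`` returns a copy of the
    input.  Used to bring velocity/acceleration streams (which lose one and
    two frames to finite differencing) back to the common sequence length.
    """
    x = np.asarray(x, dtype=np.float64)
    t = x.shape[0]
    if t < 2:
        raise ValidationError("need at least 2 rows to interpolate")
    if length < 1:
        raise ValidationError("target length must be >= 1")
    if length == t:
        return x.copy()
    if length == 1:
        return x[:1].copy()
    pos = np.linspace(0.0, t - 1.0, length)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, t - 1)
    frac = (pos - lo).reshape((length,) + (1,) * (x.ndim - 1))
    return (1.0 - frac) * x[lo] + frac * x[hi]


def resample_sequence(seq: SkeletonSequence, length: int) -> SkeletonSequence:
    return SkeletonSequence(coords=interpolate_to_length(seq.coords, length),
                            label=seq.label, sample_id=seq.sample_id)
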