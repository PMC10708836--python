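"""Synthetic 20-joint skeleton actions with class-distinct kinematics.

The generator emulates the *shape* of depth-sensor action datasets (fixed
20-joint skeletons, variable-length sequences, many subjects, coordinate
noise) without any claim to biomechanical realism.  Each class is a set of
sinusoidal motion terms applied to the member joints of one or more body
parts on top of a standing template pose; every sample additionally gets a
random rigid transform (translation + rotation about the vertical axis),
Gaussian coordinate noise, and a jittered sequence length.

Sinusoidal limb motion is the minimal kinematics that gives all five input
streams signal: parts move (part stream), hand geometry changes (joint
stream), and the derivatives are non-trivial (velocity and acceleration
streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton_core import (DEFAULT_JOINT_MAP, DatasetManifest, JointIndexMap,
                            ManifestEntry, SkeletonSequence, ValidationError,
                            save_manifest, save_sequence)

# Standing template pose, meters, z up.  Rows are joints 1..20:
# trunk center 1; trunk members 2 (neck), 3 (head), 16 (pelvis);
# LA 7 (shoulder) -> 8 (elbow), 19 (wrist), 9 (hand); RA mirrored: 4, 5, 17, 6;
# LL 13 (hip) -> 14 (knee), 20 (ankle), 15 (foot); RL mirrored: 10, 11, 18, 12.
BASE_POSE = np.array([
    [0.00, 0.00, 1.20],    # 1  trunk center (chest)
    [0.00, 0.00, 1.45],    # 2  neck
    [0.00, 0.00, 1.60],    # 3  head
    [0.20, 0.00, 1.35],    # 4  right shoulder
    [0.25, 0.00, 1.05],    # 5  right elbow
    [0.25, 0.05, 0.70],    # 6  right hand
    [-0.20, 0.00, 1.35],   # 7  left shoulder
    [-0.25, 0.00, 1.05],   # 8  left elbow
    [-0.25, 0.05, 0.70],   # 9  left hand
    [0.10, 0.00, 0.90],    # 10 right hip
    [0.10, 0.00, 0.50],    # 11 right knee
    [0.10, 0.20, 0.02],    # 12 right foot
    [-0.10, 0.00, 0.90],   # 13 left hip
    [-0.10, 0.00, 0.50],   # 14 left knee
    [-0.10, 0.20, 0.02],   # 15 left foot
    [0.00, 0.00, 0.95],    # 16 pelvis
    [0.25, 0.02, 0.80],    # 17 right wrist
    [0.10, 0.10, 0.10],    # 18 right ankle
    [-0.25, 0.02, 0.80],   # 19 left wrist
    [-0.10, 0.10, 0.10],   # 20 left ankle
])

SKELETON_HEIGHT = 1.60  # head z of the template, meters


@dataclass(frozen=True)
class MotionTerm:
    """One sinusoidal trajectory term applied to a part's member joints."""
    part: str
    amplitude: float            # meters
    frequency: float            # cycles per sequence
    phase: float = 0.0          # radians
    axis: tuple = (0.0, 1.0, 0.3)   # displacement direction (normalized)


@dataclass
class SyntheticSpec:
    n_classes: int = 5
    n_per_class: int = 100
    frames: int = 64
    noise_sd: float = 0.02 * SKELETON_HEIGHT
    base_pose: np.ndarray = field(default_factory=lambda: BASE_POSE.copy())
    class_motions: list = None          # list (per class) of MotionTerm lists
    translation_range: float = 0.5      # uniform per-axis shift, meters
    rotation_range: float = np.pi / 6   # uniform yaw about z, radians
    length_jitter: float = 0.25         # fractional sequence-length spread
    seed: int = 0
    jmap: JointIndexMap = field(default_factory=lambda: DEFAULT_JOINT_MAP)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.frames < 8:
            raise ValidationError("need at least 8 frames")
        if self.class_motions is None:
            self.class_motions = default_class_motions(self.n_classes)
        if len(self.class_motions) != self.n_classes:
            raise ValidationError(
                f"class_motions has {len(self.class_motions)} entries for "
                f"{self.n_classes} classes")
        signatures = [frozenset((t.part, t.frequency)
                                for t in terms)
                      for terms in self.class_motions]
        for c, terms in enumerate(self.class_motions):
            if not any(t.amplitude > 0 for t in terms):
                raise ValidationError(f"class {c} has no positive amplitude")
        for a in range(self.n_classes):
            for b in range(a + 1, self.n_classes):
                if signatures[a] == signatures[b]:
                    raise ValidationError(
                        f"classes {a} and {b} have identical motion "
                        "(part, frequency) signatures")


#: frozen library of class kinematics; the first ``n_classes`` entries are
#: used.  Amplitudes were fixed once against the nearest-centroid
#: separability oracle and are shipped as package constants.
_MOTION_LIBRARY = [
    # 0: one-arm lift (left arm swings forward/up)
    [MotionTerm("LA", 0.30, 1.0, axis=(0.0, 0.8, 0.6))],
    # 1: squat (both legs flex, trunk dips)
    [MotionTerm("LL", 0.22, 0.8, axis=(0.0, 0.3, -1.0)),
     MotionTerm("RL", 0.22, 0.8, axis=(0.0, 0.3, -1.0)),
     MotionTerm("TRUNK", 0.10, 0.8, axis=(0.0, 0.2, -1.0))],
    # 2: hammering (right arm, fast small strokes)
    [MotionTerm("RA", 0.18, 3.0, axis=(0.0, 0.9, -0.5))],
    # 3: walking-in-place (legs antiphase)
    [MotionTerm("LL", 0.25, 1.5, axis=(0.0, 1.0, 0.2)),
     MotionTerm("RL", 0.25, 1.5, phase=np.pi, axis=(0.0, 1.0, 0.2))],
    # 4: two-hand carry sway (both arms, slow, lateral)
    [MotionTerm("LA", 0.20, 0.5, axis=(1.0, 0.3, 0.0)),
     MotionTerm("RA", 0.20, 0.5, axis=(1.0, 0.3, 0.0))],
    # 5: overhead wave (left arm, fast)
    [MotionTerm("LA", 0.25, 2.5, axis=(0.3, 0.0, 1.0))],
    # 6: kicking (right leg, large forward)
    [MotionTerm("RL", 0.35, 1.0, axis=(0.0, 1.0, 0.3))],
    # 7: bend-over (trunk, slow deep)
    [MotionTerm("TRUNK", 0.25, 0.5, axis=(0.0, 1.0, -0.5))],
]


def default_class_motions(n_classes: int) -> list:
    if n_classes > len(_MOTION_LIBRARY):
        raise ValidationError(
            f"default motion library covers up to {len(_MOTION_LIBRARY)} "
            "classes; supply class_motions explicitly")
    return [list(_MOTION_LIBRARY[c]) for c in range(n_classes)]


def _yaw(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _render(spec: SyntheticSpec, label: int, t_frames: int,
            rng: np.random.Generator) -> np.ndarray:
    """One sample: template + class motion + rigid transform + noise."""
    tgrid = np.linspace(0.0, 1.0, t_frames)
    coords = np.repeat(spec.base_pose[None, :, :], t_frames, axis=0)
    for term in spec.class_motions[label]:
        center, members = spec.jmap.part_membership[term.part]
        axis = np.asarray(term.axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        # raised-cosine excursion: the part repeatedly swings away from the
        # rest pose and back, so the mean posture also carries class signal
        wave = term.amplitude * 0.5 * (1.0 - np.cos(
            2.0 * np.pi * term.frequency * tgrid + term.phase))
        # members move fully; the center follows at one third (soft joint)
        for j, w in [(center, 1.0 / 3.0)] + [(m, 1.0) for m in members]:
            coords[:, spec.jmap.idx(j), :] += np.outer(wave * w, axis)
    rot = _yaw(rng.uniform(-spec.rotation_range, spec.rotation_range))
    shift = rng.uniform(-spec.translation_range, spec.translation_range, 3)
    coords = coords @ rot.T + shift
    coords += rng.normal(0.0, spec.noise_sd, coords.shape)
    return coords


def generate(spec: SyntheticSpec, out_dir=None
             ) -> tuple[list, DatasetManifest]:
    """Generate a balanced labeled dataset, deterministically from the seed.

    With ``out_dir`` set, sequences are written as ``.npz`` containers and
    the manifest (with resolvable paths) as ``manifest.json``; otherwise the
    manifest entries carry empty paths and the sequences live in memory.
    """
    rng = np.random.default_rng(spec.seed)
    sequences, entries = [], []
    class_names = [f"class_{c}" for c in range(spec.n_classes)]
    for c in range(spec.n_classes):
        for i in range(spec.n_per_class):
            if spec.length_jitter > 0:
                lo = max(3, int(round(spec.frames * (1 - spec.length_jitter))))
                hi = int(round(spec.frames * (1 + spec.length_jitter)))
                t_frames = int(rng.integers(lo, hi + 1))
            else:
                t_frames = spec.frames
            sid = f"c{c:02d}_s{i:04d}"
            coords = _render(spec, c, t_frames, rng)
            seq = SkeletonSequence(coords=coords, label=c, sample_id=sid)
            sequences.append(seq)
            path = ""
            if out_dir is not None:
                # store the bare filename: manifest entries resolve
                # relative to the manifest's own folder at load time
                path = f"{sid}.npz"
                save_sequence(seq, Path(out_dir) / path)
            entries.append(ManifestEntry(path=path, label=c, sample_id=sid))
    manifest = DatasetManifest(entries=entries, class_names=class_names,
                               n_classes=spec.n_classes)
    if out_dir is not None:
        save_manifest(manifest, Path(out_dir) / "manifest.json")
    return sequences, manifest


def separability_oracle(sequences, labels, train_frac: float = 0.7,
                        seed: int = 0) -> float:
    """Model-free class-separability lower bound.

    Nearest-class-centroid accuracy on time-averaged part-level features
    under a seeded train/test split.  Any trained model worth its cost
    should not fall far below this number on the same data.
    """
    from sklearn.neighbors import NearestCentroid

    from .feature_streams import part_level

    labels = np.asarray(labels)
    feats = np.stack([
        np.mean([part_level(f) for f in seq.coords], axis=0)
        for seq in sequences])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    n_train = int(round(train_frac * len(labels)))
    tr, te = order[:n_train], order[n_train:]
    clf = NearestCentroid()
    clf.fit(feats[tr], labels[tr])
    return float((clf.predict(feats[te]) == labels[te]).mean())


def two_class_spec(seed: int = 0, n_per_class: int = 30) -> SyntheticSpec:
    """Frozen desk fixture: lift vs squat."""
    return SyntheticSpec(n_classes=2, n_per_class=n_per_class, seed=seed)


def five_class_spec(seed: int = 0, n_per_class: int = 100) -> SyntheticSpec:
    """Frozen desk fixture: 5 classes x 100 samples (500 total)."""
    return SyntheticSpec(n_classes=5, n_per_class=n_per_class, seed=seed)
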