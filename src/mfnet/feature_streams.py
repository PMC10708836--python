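"""The five input streams: body, part, joint, velocity, acceleration.

Spatial streams describe each frame at three scales:

* **body** — raw joint coordinates, one node-feature matrix per frame.
* **part** — the body split into five parts (left/right arm, left/right leg,
  trunk); per part, the three member-minus-center difference vectors, e.g.
  for the left arm ``concat(s8 - s7, s19 - s7, s9 - s7)``.  45 values per
  frame (5 parts x 3 members x 3 coords), translation invariant.
* **joint** — hand-centric geometry: the Euclidean distance from every joint
  to each hand (JJED, 40 values) and the unit direction vector from every
  joint to each hand (JJO, 120 values); manual actions are dominated by hand
  configuration, which these features expose directly.

Temporal streams are the finite-difference kinematics
``V_t = P_{t+1} - P_t`` and ``A_t = V_{t+1} - V_t``, linearly interpolated
back to the common sequence length so all five streams align frame-for-frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton_core import (DEFAULT_JOINT_MAP, PART_ORDER, JointIndexMap,
                            SkeletonSequence, ValidationError,
                            interpolate_to_length)

STREAM_NAMES = ("body", "part", "joint", "velocity", "acceleration")

PART_DIM = 45     # 5 parts x 3 member vectors x 3 coords
JJED_DIM = 40     # 20 joints x 2 hands
JJO_DIM = 120     # 20 joints x 2 hands x 3 coords
JOINT_DIM = JJED_DIM + JJO_DIM


@dataclass
class FeatureStream:
    name: str
    values: np.ndarray

    def __post_init__(self):
        if self.name not in STREAM_NAMES:
            raise ValidationError(f"unknown stream name {self.name!r}")


@dataclass
class ExtractConfig:
    """Stream-extraction settings: common length and frame preprocessing."""
    length: int = 64
    center_root: bool = False
    jmap: JointIndexMap = field(default_factory=lambda: DEFAULT_JOINT_MAP)


def part_level(frame: np.ndarray, jmap: JointIndexMap = DEFAULT_JOINT_MAP
               ) -> np.ndarray:
    """45-dim part feature of one frame: member-minus-center vectors, in the
    fixed part order (LA, RA, LL, RL, TRUNK)."""
    frame = np.asarray(frame, dtype=np.float64)
    out = []
    for part in PART_ORDER:
        center, members = jmap.part_membership[part]
        c = frame[jmap.idx(center)]
        for m in members:
            out.append(frame[jmap.idx(m)] - c)
    return np.concatenate(out)


def part_level_nodes(frame: np.ndarray, jmap: JointIndexMap = DEFAULT_JOINT_MAP
                     ) -> np.ndarray:
    """Part features as a (5, 9) node-feature matrix for the part graph."""
    return part_level(frame, jmap).reshape(5, 9)


def joint_level(frame: np.ndarray, jmap: JointIndexMap = DEFAULT_JOINT_MAP
                ) -> np.ndarray:
    """160-dim joint feature: JJED (left block, right block) then JJO.

    The orientation for a joint coinciding with the hand is the zero vector
    (guarded division).
    """
    frame = np.asarray(frame, dtype=np.float64)
    dists, orients = [], []
    for hand in jmap.hand_joints:
        h = frame[jmap.idx(hand)]
        vec = h[None, :] - frame            # joint -> hand
        d = np.linalg.norm(vec, axis=1)
        unit = np.zeros_like(vec)
        nz = d > 0
        unit[nz] = vec[nz] / d[nz, None]
        dists.append(d)
        orients.append(unit.ravel())
    return np.concatenate(dists + orients)


def joint_level_all_pairs(frame: np.ndarray) -> np.ndarray:
    """All-pairs variant: distances for every unordered joint pair (190)."""
    frame = np.asarray(frame, dtype=np.float64)
    iu = np.triu_indices(frame.shape[0], k=1)
    diff = frame[iu[0]] - frame[iu[1]]
    return np.linalg.norm(diff, axis=1)


def motion(seq: SkeletonSequence) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration streams, resampled to the input length T.

    Raw finite differences have lengths T-1 and T-2; both are linearly
    interpolated back to T.
    """
    if seq.n_frames < 3:
        raise ValidationError("motion features need at least 3 frames")
    v = np.diff(seq.coords, n=1, axis=0)
    a = np.diff(v, n=1, axis=0)
    t = seq.n_frames
    return interpolate_to_length(v, t), interpolate_to_length(a, t)


def body_level(seq: SkeletonSequence, center_root: bool = False,
               jmap: JointIndexMap = DEFAULT_JOINT_MAP) -> np.ndarray:
    """Raw (T, 20, 3) coordinates; optionally re-expressed relative to the
    trunk center joint every frame."""
    coords = seq.coords.copy()
    if center_root:
        root = jmap.part_membership["TRUNK"][0]
        coords -= coords[:, jmap.idx(root), None, :]
    return coords


def extract_all(seq: SkeletonSequence, config: ExtractConfig | None = None
                ) -> list[FeatureStream]:
    """All five streams of one sequence at the common configured length.

    Coordinates are first resampled to ``config.length``; spatial features
    are computed per resampled frame, while velocity/acceleration are
    differenced on the original sequence and then interpolated to the same
    length.
    """
    config = config or ExtractConfig()
    jmap = config.jmap
    L = config.length
    coords = interpolate_to_length(seq.coords, L)
    rs = SkeletonSequence(coords=coords, label=seq.label,
                          sample_id=seq.sample_id)
    body = body_level(rs, center_root=config.center_root, jmap=jmap)
    part = np.stack([part_level_nodes(f, jmap) for f in coords])
    joint = np.stack([joint_level(f, jmap) for f in coords])
    v_raw = np.diff(seq.coords, n=1, axis=0)
    a_raw = np.diff(v_raw, n=1, axis=0)
    vel = interpolate_to_length(v_raw, L)
    acc = interpolate_to_length(a_raw, L)
    return [
        FeatureStream("body", body),
        FeatureStream("part", part),
        FeatureStream("joint", joint),
        FeatureStream("velocity", vel),
        FeatureStream("acceleration", acc),
    ]
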