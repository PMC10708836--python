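"""Part, joint, motion and body streams, and the combined extractor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfnet.feature_streams import (JOINT_DIM, PART_DIM, ExtractConfig,
                                   body_level, extract_all, joint_level,
                                   joint_level_all_pairs, motion, part_level)
from mfnet.skeleton_core import (DEFAULT_JOINT_MAP, SkeletonSequence,
                                 ValidationError)


def _frames(seed, n=1):
    rng = np.random.default_rng(seed)
    f = rng.normal(scale=0.5, size=(n, 20, 3))
    return f[0] if n == 1 else f


class TestPartLevel:
    def test_zero_frame(self):
        assert np.array_equal(part_level(np.zeros((20, 3))),
                              np.zeros(PART_DIM))

    def test_single_displaced_member(self):
        # joint 8 is the first member of the first part (left arm, center 7):
        # its difference lands in components 0..2, the rest stay zero
        frame = np.zeros((20, 3))
        frame[DEFAULT_JOINT_MAP.idx(8)] = (1.0, 0.0, 0.0)
        out = part_level(frame)
        assert np.array_equal(out[:3], [1.0, 0.0, 0.0])
        assert np.array_equal(out[3:], np.zeros(42))

    def test_member_order_within_part(self):
        # left-arm members are concatenated in the order (8, 19, 9)
        frame = np.zeros((20, 3))
        for pos, j in enumerate((8, 19, 9)):
            frame[DEFAULT_JOINT_MAP.idx(j)] = (pos + 1.0, 0.0, 0.0)
        out = part_level(frame)
        assert np.array_equal(out[:9].reshape(3, 3)[:, 0], [1.0, 2.0, 3.0])

    def test_fixed_concatenation_order_golden(self):
        # joint j at (j, 2j, 3j): the member-minus-center differences have a
        # closed form (m - c) * (1, 2, 3), frozen here per part in the order
        # LA, RA, LL, RL, TRUNK
        frame = np.arange(1, 21)[:, None] * np.array([1.0, 2.0, 3.0])
        expect = []
        for center, members in [(7, (8, 19, 9)), (4, (5, 17, 6)),
                                (13, (14, 20, 15)), (10, (11, 18, 12)),
                                (1, (2, 3, 16))]:
            for m in members:
                expect.extend([(m - center) * k for k in (1.0, 2.0, 3.0)])
        assert np.allclose(part_level(frame), expect)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), shift=st.tuples(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)))
    def test_translation_invariance(self, seed, shift):
        frame = _frames(seed)
        assert np.allclose(part_level(frame + np.array(shift)),
                           part_level(frame))


class TestJointLevel:
    def test_dimensions(self):
        assert joint_level(_frames(0)).shape == (JOINT_DIM,)

    def test_distance_and_orientation_to_left_hand(self):
        frame = np.zeros((20, 3))
        left = DEFAULT_JOINT_MAP.hand_joints[0]
        frame[DEFAULT_JOINT_MAP.idx(3)] = (3.0, 4.0, 0.0)
        out = joint_level(frame)
        # left-hand distance block comes first, indexed by joint row
        assert np.isclose(out[DEFAULT_JOINT_MAP.idx(3)], 5.0)
        # orientation from joint 3 to the left hand (at origin): (-3,-4,0)/5
        jjo = out[40:].reshape(2, 20, 3)
        assert np.allclose(jjo[0, DEFAULT_JOINT_MAP.idx(3)],
                           (-0.6, -0.8, 0.0))
        # hand-to-itself: zero distance, zero orientation (guarded division)
        assert out[DEFAULT_JOINT_MAP.idx(left)] == 0.0
        assert np.array_equal(jjo[0, DEFAULT_JOINT_MAP.idx(left)],
                              np.zeros(3))

    def test_orientation_unit_norm_or_zero(self):
        frame = _frames(1)
        # force one exact coincidence with the right hand
        right = DEFAULT_JOINT_MAP.hand_joints[1]
        frame[DEFAULT_JOINT_MAP.idx(2)] = frame[DEFAULT_JOINT_MAP.idx(right)]
        jjo = joint_level(frame)[40:].reshape(2, 20, 3)
        norms = np.linalg.norm(jjo, axis=2)
        assert np.all((np.isclose(norms, 1.0)) | (norms == 0.0))
        assert norms[1, DEFAULT_JOINT_MAP.idx(2)] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), shift=st.tuples(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)))
    def test_translation_invariance(self, seed, shift):
        frame = _frames(seed)
        assert np.allclose(joint_level(frame + np.array(shift)),
                           joint_level(frame))

    def test_all_pairs_variant(self):
        out = joint_level_all_pairs(_frames(2))
        assert out.shape == (190,)
        assert (out >= 0).all()


class TestMotion:
    def test_constant_sequence_is_still(self):
        seq = SkeletonSequence(np.ones((6, 20, 3)))
        v, a = motion(seq)
        assert np.allclose(v, 0.0) and np.allclose(a, 0.0)

    def test_linear_motion(self):
        u = np.array([1.0, -2.0, 0.5])
        coords = np.arange(8)[:, None, None] * u[None, None, :] * np.ones(
            (8, 20, 3))
        v, a = motion(SkeletonSequence(coords))
        assert np.allclose(v, u)
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_quadratic_finite_differences(self):
        # one coordinate follows t^2 = (0, 1, 4, 9): raw V = (1, 3, 5),
        # raw A = (2, 2); outputs are those, re-interpolated to length 4
        coords = np.zeros((4, 20, 3))
        coords[:, 0, 0] = [0.0, 1.0, 4.0, 9.0]
        v, a = motion(SkeletonSequence(coords))
        from mfnet.skeleton_core import interpolate_to_length
        assert np.allclose(v[:, 0, 0],
                           interpolate_to_length(
                               np.array([[1.0], [3.0], [5.0]]), 4).ravel())
        assert np.allclose(a[:, 0, 0], 2.0)

    def test_translation_invariant_scale_equivariant(self, rng):
        coords = rng.normal(size=(7, 20, 3))
        v, a = motion(SkeletonSequence(coords))
        v2, a2 = motion(SkeletonSequence(coords + 3.3))
        assert np.allclose(v, v2) and np.allclose(a, a2)
        v3, a3 = motion(SkeletonSequence(coords * 2.0))
        assert np.allclose(v3, 2 * v) and np.allclose(a3, 2 * a)


class TestBodyLevel:
    def test_identity_passthrough(self, short_sequence):
        assert np.array_equal(body_level(short_sequence),
                              short_sequence.coords)

    def test_root_centering(self, short_sequence):
        out = body_level(short_sequence, center_root=True)
        root = DEFAULT_JOINT_MAP.idx(1)
        assert np.allclose(out[:, root], 0.0)


class TestExtractAll:
    def test_five_streams_common_length(self, short_sequence):
        streams = extract_all(short_sequence, ExtractConfig(length=8))
        assert [s.name for s in streams] == [
            "body", "part", "joint", "velocity", "acceleration"]
        assert all(s.values.shape[0] == 8 for s in streams)
        shapes = {s.name: s.values.shape for s in streams}
        assert shapes["body"] == (8, 20, 3)
        assert shapes["part"] == (8, 5, 9)
        assert shapes["joint"] == (8, JOINT_DIM)
        assert shapes["velocity"] == (8, 20, 3)
        assert shapes["acceleration"] == (8, 20, 3)

    def test_deterministic(self, short_sequence):
        a = extract_all(short_sequence)
        b = extract_all(short_sequence)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)
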