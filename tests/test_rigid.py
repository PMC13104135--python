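"""Rigid alignment pipeline: detection, matching, consistency filtering,
closed-form estimation and sequential propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emalign import (Keypoint, RigidTransform, align_stack_rigid,
                     apply_rigid, detect_keypoints, edge_mask, estimate_rigid,
                     filter_edge_keypoints, lpm_filter, match_bidirectional,
                     slice_volume, generate_phantom)
from emalign.evaluation import ssim

from conftest import interior


def _kps_from_positions(positions, descriptors):
    return [Keypoint(tuple(p), 1.0, np.asarray(d, dtype=np.float64))
            for p, d in zip(positions, descriptors)]


class TestDetect:
    def test_constant_image_no_keypoints(self):
        assert detect_keypoints(np.full((64, 64), 0.5)) == []

    def test_deterministic(self, textured_slice):
        a = detect_keypoints(textured_slice, 200)
        b = detect_keypoints(textured_slice, 200)
        assert len(a) == len(b) > 0
        for ka, kb in zip(a, b):
            assert ka.position == kb.position
            np.testing.assert_array_equal(ka.descriptor, kb.descriptor)

    def test_enough_keypoints_on_phantom(self):
        img = generate_phantom((16, 256, 256), seed=0)[8]
        assert len(detect_keypoints(img, 500)) >= 50

    def test_descriptors_unit_norm_positions_in_bounds(self, textured_slice):
        for kp in detect_keypoints(textured_slice, 200):
            assert abs(np.linalg.norm(kp.descriptor) - 1.0) < 1e-6
            assert 0 <= kp.position[0] < textured_slice.shape[0]
            assert 0 <= kp.position[1] < textured_slice.shape[1]

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_keypoints(np.zeros((16, 16)))


class TestEdgeMask:
    def test_constant_image_all_false(self):
        assert not edge_mask(np.full((32, 32), 0.3)).any()

    def test_step_edge_band(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        mask = edge_mask(img, dilate_r=2)
        assert mask[:, 30:34].all()
        assert not mask[:, :24].any() and not mask[:, 40:].any()

    def test_dilate_zero_is_raw_edges(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        m0 = edge_mask(img, dilate_r=0)
        m2 = edge_mask(img, dilate_r=2)
        assert m0.sum() < m2.sum()

    def test_invalid_thresholds(self, textured_slice):
        with pytest.raises(ValueError):
            edge_mask(textured_slice, low=0.5, high=0.2)


class TestFilterEdgeKeypoints:
    def test_trivial_masks(self, textured_slice):
        kps = detect_keypoints(textured_slice, 100)
        assert filter_edge_keypoints(kps, np.ones(textured_slice.shape, bool)) == kps
        assert filter_edge_keypoints(kps, np.zeros(textured_slice.shape, bool)) == []

    def test_matches_per_point_lookup(self, textured_slice, rng):
        kps = detect_keypoints(textured_slice, 100)
        mask = rng.random(textured_slice.shape) > 0.5
        kept = filter_edge_keypoints(kps, mask)
        expected = [k for k in kps
                    if mask[int(round(k.position[0])), int(round(k.position[1]))]]
        assert kept == expected


class TestMatchBidirectional:
    def test_identical_descriptor_sets(self, rng):
        desc = rng.standard_normal((10, 8))
        desc /= np.linalg.norm(desc, axis=1, keepdims=True)
        kps = _kps_from_positions(rng.random((10, 2)) * 50, desc)
        ms = match_bidirectional(kps, kps)
        assert sorted(map(tuple, ms.pairs)) == [(i, i) for i in range(10)]

    def test_non_mutual_pair_rejected(self):
        # a1's NN is b2, but b2's NN is a3 -> (a1, b2) must not appear.
        a = _kps_from_positions([(0, 0), (1, 1), (2, 2)],
                                [[1.0, 0.0], [0.0, 1.0], [0.93, 0.07]])
        b = _kps_from_positions([(0, 0), (1, 1), (2, 2)],
                                [[0.0, 0.9], [0.95, 0.05], [0.1, 0.9]])
        d = np.linalg.norm(
            np.array([k.descriptor for k in a])[:, None]
            - np.array([k.descriptor for k in b])[None], axis=-1)
        assert d[0].argmin() == 1 and d[:, 1].argmin() == 2  # fixture sanity
        ms = match_bidirectional(a, b)
        accepted = set(map(tuple, ms.pairs))
        assert (0, 1) not in accepted
        # brute-force mutual-NN oracle over all 9 distances
        oracle = {(i, int(d[i].argmin())) for i in range(3)
                  if int(d[:, d[i].argmin()].argmin()) == i}
        assert accepted == oracle

    def test_partial_one_to_one(self, rng):
        a = _kps_from_positions(rng.random((20, 2)), rng.standard_normal((20, 6)))
        b = _kps_from_positions(rng.random((15, 2)), rng.standard_normal((15, 6)))
        ms = match_bidirectional(a, b)
        assert len(set(ms.pairs[:, 0])) == len(ms.pairs)
        assert len(set(ms.pairs[:, 1])) == len(ms.pairs)

    def test_symmetry(self, rng):
        a = _kps_from_positions(rng.random((12, 2)), rng.standard_normal((12, 6)))
        b = _kps_from_positions(rng.random((12, 2)), rng.standard_normal((12, 6)))
        fwd = set(map(tuple, match_bidirectional(a, b).pairs))
        rev = {(j, i) for i, j in match_bidirectional(b, a).pairs}
        assert fwd == rev

    def test_empty_side(self):
        kps = _kps_from_positions([(0, 0)], [[1.0, 0.0]])
        assert len(match_bidirectional([], kps)) == 0


class TestLpmFilter:
    @staticmethod
    def _grid_matches(n=6, jitter=None):
        rows, cols = np.meshgrid(np.arange(n) * 10.0, np.arange(n) * 10.0,
                                 indexing="ij")
        src_pos = np.stack([rows.ravel(), cols.ravel()], axis=1)
        tgt_pos = src_pos + 5.0  # one global translation
        if jitter is not None:
            tgt_pos = tgt_pos.copy()
            tgt_pos[jitter] += 200.0
        desc = np.eye(len(src_pos))
        src = _kps_from_positions(src_pos, desc)
        tgt = _kps_from_positions(tgt_pos, desc)
        matches = match_bidirectional(src, tgt)
        return src, tgt, matches

    def test_global_transform_all_kept(self):
        src, tgt, ms = self._grid_matches()
        out = lpm_filter(src, tgt, ms, K=6, tau=0.5, passes=2)
        assert len(out) == len(ms) == 36

    def test_single_displaced_match_removed(self):
        src, tgt, ms = self._grid_matches(jitter=14)
        out = lpm_filter(src, tgt, ms, K=6, tau=0.5, passes=2)
        removed = set(map(tuple, ms.pairs)) - set(map(tuple, out.pairs))
        assert removed == {(14, 14)}

    def test_tau_zero_removes_nothing(self):
        src, tgt, ms = self._grid_matches(jitter=14)
        assert len(lpm_filter(src, tgt, ms, K=6, tau=0.0, passes=2)) == len(ms)

    def test_too_few_matches_passthrough(self):
        src, tgt, ms = self._grid_matches()
        small = type(ms)(ms.pairs[:4], ms.distances[:4])
        out = lpm_filter(src, tgt, small, K=6)
        assert len(out) == 4


class TestEstimateRigid:
    def test_identity_on_equal_sets(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        T, rms = estimate_rigid(X, X)
        assert abs(T.theta_deg) < 1e-12 and np.allclose(T.t, 0) and rms < 1e-12

    def test_forward_constructed_transform_recovered(self, rng):
        X = rng.random((20, 2)) * 100
        gt = RigidTransform(30.0, (5.0, -3.0))
        # construct Y so that gt maps Y onto X
        A, b = gt.as_matrix()
        Y = (X - b) @ np.linalg.inv(A).T
        T, rms = estimate_rigid(X, Y)
        assert abs(T.theta_deg - 30.0) < 1e-9
        assert np.allclose(T.t, (5.0, -3.0), atol=1e-9)
        assert rms < 1e-9

    def test_reflection_corrected(self, rng):
        X = rng.random((15, 2)) * 50
        Y = X.copy()
        Y[:, 1] *= -1  # mirrored
        T, rms = estimate_rigid(X, Y)
        assert np.linalg.det(T.R) > 0.999999
        assert rms > 0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_rigid(np.zeros((1, 2)), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            estimate_rigid(np.zeros((5, 2)), np.zeros((5, 2)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-180, 180), st.integers(0, 100))
    def test_equivariance_under_prerotation(self, q_deg, seed):
        """Pre-rotating both point sets by Q conjugates the estimate."""
        rng = np.random.default_rng(seed)
        X = rng.random((10, 2)) * 100
        gt = RigidTransform(25.0, (4.0, 1.0))
        A, b = gt.as_matrix()
        Y = (X - b) @ np.linalg.inv(A).T
        Q = RigidTransform(q_deg, (0.0, 0.0))
        T1, _ = estimate_rigid(Q.apply_points(X), Q.apply_points(Y))
        # conjugation: T1 = Q o gt o Q^-1 preserves the rotation angle
        diff = (T1.theta_deg - gt.theta_deg + 180) % 360 - 180
        assert abs(diff) < 1e-8


class TestApplyRigid:
    def test_identity_pixel_identical(self, textured_slice):
        out = apply_rigid(textured_slice, RigidTransform.identity())
        np.testing.assert_array_equal(out, textured_slice)

    def test_translation_moves_delta(self):
        img = np.zeros((32, 32))
        img[10, 10] = 1.0
        out = apply_rigid(img, RigidTransform(0.0, (5.0, 0.0)))
        assert np.unravel_index(out.argmax(), out.shape) == (15, 10)

    def test_inverse_round_trip(self, textured_slice):
        T = RigidTransform(12.0, (4.0, -6.0),
                           ((textured_slice.shape[0] - 1) / 2,) * 2)
        back = apply_rigid(apply_rigid(textured_slice, T), T.inverse())
        assert ssim(interior(back, 24), interior(textured_slice, 24)) > 0.98


class TestAlignStackRigid:
    def test_near_identity_on_undistorted_stack(self):
        # per-pair angle noise on natural content is ~0.02 deg and random-
        # walks over the 15 pairs; 0.3 deg bounds the cumulative drift
        stack = slice_volume(generate_phantom((16, 512, 512), seed=13,
                                              drift_px=0.0), 1)
        _, transforms = align_stack_rigid(stack)
        assert max(np.hypot(*T.t) for T in transforms) < 0.5
        assert max(abs(T.theta_deg) for T in transforms) < 0.3

    def test_requires_two_slices(self, textured_slice):
        with pytest.raises(ValueError):
            align_stack_rigid(np.asarray(textured_slice)[None])

    def test_single_resample_beats_repeated(self, phantom_stack):
        """Resampling the original slice once under the cumulative transform
        loses less detail than compounding two partial resamples."""
        from emalign import apply_rigid_jitter
        jit, gt = apply_rigid_jitter(phantom_stack, t_max=8, theta_max=8, seed=9)
        i = 6
        cum = gt.transforms[i].inverse()
        single = apply_rigid(jit[i], cum)
        # exact two-step decomposition cum = T_a o T_b, resampled twice
        T_b = RigidTransform(cum.theta_deg / 2,
                             (cum.t[0] / 2, cum.t[1] / 2), cum.center)
        T_a = cum.compose(T_b.inverse())
        repeated = apply_rigid(apply_rigid(jit[i], T_b), T_a)
        gt_img = phantom_stack[i]
        s_single = ssim(interior(single, 24), interior(gt_img, 24))
        s_repeated = ssim(interior(repeated, 24), interior(gt_img, 24))
        assert s_single >= s_repeated
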