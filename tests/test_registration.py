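"""Coarse alignment, coherent point drift, Procrustes, thin-plate splines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from seg2fe.registration import (
    CorrespondedSets,
    SimilarityTransform,
    TPSTransform,
    coarse_align,
    cpd_nonrigid,
    cpd_rigid,
    gpa,
    gpa_objective,
    load_transform,
    robust_initial_pose,
    save_transform,
    tps_apply,
    tps_fit,
    umeyama,
)


def skewed_cloud(n=200, seed=0):
    """Cloud with distinct principal axes and nonzero third moments."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3)) * [3.0, 2.0, 1.0]
    pts[:, 0] += 0.05 * pts[:, 0] ** 2  # skew along x
    pts[:, 1] += 0.04 * pts[:, 1] ** 2
    pts[:, 2] += 0.06 * pts[:, 2] ** 2
    return pts


class TestCoarseAlign:
    def test_self_alignment_is_identity(self):
        pts = skewed_cloud()
        t = coarse_align(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert abs(t.scale - 1) < 1e-12

    def test_recovers_similarity_transform(self):
        pts = skewed_cloud()
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = 1.5 * pts @ R.T + [5.0, 0, 0]
        t = coarse_align(pts, moved)
        np.testing.assert_allclose(t.apply(pts), moved, atol=1e-6)

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(1)
        flat = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        with pytest.raises(ValueError, match="coplanar"):
            coarse_align(flat, skewed_cloud())


class TestCPDRigid:
    def test_identity_on_equal_clouds(self):
        pts = skewed_cloud(150)
        t = cpd_rigid(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t.translation, 0, atol=1e-6)
        assert abs(t.scale - 1) < 1e-6

    def test_recovers_known_rotation(self):
        pts = skewed_cloud(150)
        axis = np.array([0.3, -0.5, 0.8])
        R = Rotation.from_rotvec(np.deg2rad(25) * axis / np.linalg.norm(axis)).as_matrix()
        target = pts @ R.T + [3.0, -2.0, 1.0]
        t = cpd_rigid(pts, target)
        err = Rotation.from_matrix(t.rotation @ R.T).magnitude()
        assert err < 1e-3

    def test_robust_to_outliers(self):
        rng = np.random.default_rng(3)
        pts = skewed_cloud(200)
        R = Rotation.from_euler("y", 20, degrees=True).as_matrix()
        target = pts @ R.T
        n_out = 20
        target[rng.choice(200, n_out, replace=False)] = rng.uniform(-8, 8, (n_out, 3))
        t = cpd_rigid(pts, target, w=0.1)
        err = Rotation.from_matrix(t.rotation @ R.T).magnitude()
        assert err < 1e-2

    def test_equivariance_under_common_rotation(self):
        pts = skewed_cloud(120)
        R = Rotation.from_euler("x", 15, degrees=True).as_matrix()
        target = pts @ R.T + [1.0, 2, 3]
        t = cpd_rigid(pts, target)
        Q = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        t_rot = cpd_rigid(pts @ Q.T, target @ Q.T)
        np.testing.assert_allclose(t_rot.rotation, Q @ t.rotation @ Q.T, atol=1e-4)


class TestCPDNonrigid:
    def test_identity_on_equal_clouds(self):
        pts = skewed_cloud(120)
        out = cpd_nonrigid(pts, pts)
        scale = np.linalg.norm(pts.std(axis=0))
        assert np.abs(out - pts).max() < 1e-5 * scale

    def test_reduces_distance_under_smooth_warp(self):
        pts = skewed_cloud(150, seed=5)
        warped = pts + 0.15 * np.sin(pts[:, [1, 2, 0]])
        # kernel width matched to the warp wavelength (in normalized units)
        out = cpd_nonrigid(pts, warped, beta=1.0, lam=1.0)
        before = np.linalg.norm(pts - warped, axis=1).mean()
        after = np.linalg.norm(out - warped, axis=1).mean()
        assert after < 0.2 * before

    def test_huge_lambda_suppresses_deformation(self):
        pts = skewed_cloud(100, seed=6)
        warped = pts + 0.1 * np.sin(pts[:, [1, 2, 0]])
        out = cpd_nonrigid(pts, warped, lam=1e6)
        scale = np.linalg.norm(pts.std(axis=0))
        # displacement beyond the rigid/centroid part stays negligible
        assert np.abs(out - (pts - pts.mean(0) + warped.mean(0))).max() < 1e-2 * scale


class TestGPA:
    def test_rigid_copies_collapse(self):
        rng = np.random.default_rng(7)
        shape = rng.normal(size=(40, 3))
        sets = []
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            sets.append(shape @ R.T + rng.normal(size=3) * 10)
        out = gpa(sets)
        for i in range(3):
            for j in range(i):
                rms = np.sqrt(np.mean((out.sets[i] - out.sets[j]) ** 2))
                assert rms < 1e-9

    def test_aligned_sets_are_fixed_point(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(30, 3))
        sets = [base + rng.normal(0, 0.01, base.shape) for _ in range(4)]
        pre = gpa(sets)
        again = gpa(pre.sets)
        for a, b in zip(pre.sets, again.sets):
            assert np.abs(a - b).max() < 1e-6

    def test_beats_centroid_only_alignment(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(50, 3)) * [4, 2, 1]
        sets = []
        for k in range(10):
            R = Rotation.random(random_state=100 + k).as_matrix()
            jit = base + rng.normal(0, 0.05, base.shape)
            sets.append(jit @ R.T + rng.normal(size=3))
        out = gpa(sets)
        centered = [s - s.mean(axis=0) for s in sets]
        naive = CorrespondedSets(centered)
        assert gpa_objective(out) <= gpa_objective(naive)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="K"):
            gpa([np.zeros((5, 3)), np.zeros((6, 3))])


class TestTPS:
    def test_pure_affine_recovered_without_warping(self):
        rng = np.random.default_rng(10)
        src = rng.normal(size=(30, 3))
        A = np.array([[1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.0]])
        tgt = src @ A.T + [1.0, 2.0, 3.0]
        t = tps_fit(src, tgt)
        assert np.abs(t.weights).max() < 1e-8
        np.testing.assert_allclose(t.affine_matrix, A, atol=1e-8)

    def test_exact_interpolation_at_landmarks(self):
        rng = np.random.default_rng(11)
        src = rng.normal(size=(25, 3)) * 5
        tgt = src + rng.normal(0, 0.5, src.shape)
        t = tps_fit(src, tgt)
        assert np.abs(tps_apply(t, src) - tgt).max() < 1e-8
        assert t.side_condition_residual() < 1e-8

    def test_identity_mapping(self):
        rng = np.random.default_rng(12)
        src = rng.normal(size=(20, 3))
        t = tps_fit(src, src)
        np.testing.assert_allclose(t.affine_matrix, np.eye(3), atol=1e-8)
        assert np.abs(t.weights).max() < 1e-8

    def test_affine_midpoint_linearity(self):
        rng = np.random.default_rng(13)
        src = rng.normal(size=(15, 3))
        A = np.diag([1.3, 0.8, 1.1])
        t = tps_fit(src, src @ A.T)
        p, q = rng.normal(size=(2, 3))
        mid_image = tps_apply(t, (p + q)[None] / 2)[0]
        image_mid = (tps_apply(t, p[None])[0] + tps_apply(t, q[None])[0]) / 2
        np.testing.assert_allclose(mid_image, image_mid, atol=1e-8)

    def test_large_regularization_tends_to_affine(self):
        rng = np.random.default_rng(14)
        src = rng.normal(size=(40, 3)) * 3
        tgt = src + 0.3 * np.sin(src[:, [1, 2, 0]])
        bendy = tps_fit(src, tgt, lam_tps=0.0)
        stiff = tps_fit(src, tgt, lam_tps=1e6)
        assert np.abs(stiff.weights).max() < 1e-3 * np.abs(bendy.weights).max() + 1e-12

    def test_coincident_landmarks_rejected(self):
        src = np.vstack([np.eye(3), np.eye(3)[:1], [[0.5, 0.5, 0.5]]])
        with pytest.raises(ValueError, match="coincident"):
            tps_fit(src, src)

    def test_coplanar_landmarks_rejected(self):
        src = np.column_stack([np.random.default_rng(15).normal(size=(10, 2)), np.zeros(10)])
        with pytest.raises(ValueError, match="coplanar"):
            tps_fit(src, src)


class TestTransformAlgebra:
    def test_compose_inverse_identity(self):
        rng = np.random.default_rng(16)
        R = Rotation.random(random_state=17).as_matrix()
        t = SimilarityTransform(R, rng.normal(size=3), 1.7)
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)
        comp = t.compose(t.inverse())
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-10)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="det"):
            SimilarityTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(18)
        sim = SimilarityTransform(
            Rotation.random(random_state=19).as_matrix(), rng.normal(size=3), 0.8
        )
        path = tmp_path / "sim.h5"
        save_transform(sim, path)
        back = load_transform(path)
        np.testing.assert_allclose(back.rotation, sim.rotation)
        np.testing.assert_allclose(back.translation, sim.translation)

        src = rng.normal(size=(12, 3))
        tps = tps_fit(src, src + rng.normal(0, 0.1, src.shape))
        path2 = tmp_path / "tps.h5"
        save_transform(tps, path2)
        back2 = load_transform(path2)
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(tps_apply(back2, pts), tps_apply(tps, pts), atol=1e-12)


class TestRobustPose:
    def test_recovers_flipped_alignment(self, bone_mesh):
        # a 180-degree flip about z is near-ambiguous for a two-condyle bone;
        # candidate scoring must recover the true pose
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        pts = bone_mesh.vertices[:: max(1, len(bone_mesh.vertices) // 400)]
        bad = SimilarityTransform(R, np.zeros(3))
        query = bone_mesh.surface_query()
        pose = robust_initial_pose(pts, query, bad)
        # point-to-point triage pose: sub-half-voxel accuracy is enough, the
        # callers polish with CPD afterwards
        rms = np.sqrt(np.mean(query.distance(pose.apply(pts)) ** 2))
        assert rms < 0.3
        assert Rotation.from_matrix(pose.rotation).magnitude() < 0.1


class TestTransformProperties:
    """Property-based checks of the similarity-transform group axioms."""

    @given(
        angles=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
        translation=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        scale=st.floats(0.2, 5.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_inverse_round_trip(self, angles, translation, scale, seed):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        t = SimilarityTransform(R, np.asarray(translation), scale)
        pts = np.random.default_rng(seed).normal(size=(15, 3)) * 10
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-8)

    @given(
        angles=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
        angles2=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_composition_matches_sequential_application(self, angles, angles2, seed):
        rng = np.random.default_rng(seed)
        a = SimilarityTransform(Rotation.from_euler("xyz", angles).as_matrix(), rng.normal(size=3), 1.5)
        b = SimilarityTransform(Rotation.from_euler("xyz", angles2).as_matrix(), rng.normal(size=3), 0.7)
        pts = rng.normal(size=(10, 3)) * 5
        np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9)


def test_point_set_csv_round_trip(tmp_path):
    from seg2fe.registration import load_points_csv, save_points_csv

    pts = np.random.default_rng(21).normal(size=(17, 3)) * 30
    path = tmp_path / "pts.csv"
    save_points_csv(pts, path)
    np.testing.assert_allclose(load_points_csv(path), pts, atol=1e-12)
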