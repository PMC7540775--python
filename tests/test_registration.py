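"""Kabsch solve, rigid-transform algebra, and ICP registration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from endodisp import (
    IcpParams,
    RigidTransform,
    apply_rigid_perturbation,
    apply_transform,
    icp_register,
    kabsch,
    mesh_volume,
)
from endodisp.mesh_io import MeshError


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        reflect = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(reflect, np.zeros(3))

    @given(st.integers(0, 1000))
    def test_inverse_and_compose_group_laws(self, seed):
        rng = np.random.default_rng(seed)
        tf = RigidTransform(random_rotation(seed), rng.normal(size=3))
        ident = tf.compose(tf.inverse())
        np.testing.assert_allclose(ident.matrix(), np.eye(4), atol=1e-12)
        # composition acts as matrix product on homogeneous coordinates
        other = RigidTransform(random_rotation(seed + 1), rng.normal(size=3))
        np.testing.assert_allclose(
            tf.compose(other).matrix(), tf.matrix() @ other.matrix(), atol=1e-12
        )

    def test_json_round_trip(self, tmp_path):
        tf = RigidTransform.from_axis_angle((1, 2, 2), 40.0, (0.1, -0.2, 0.3))
        path = tf.to_json(tmp_path / "tf.json")
        back = RigidTransform.from_json(path)
        np.testing.assert_allclose(back.matrix(), tf.matrix(), atol=1e-15)


class TestKabsch:
    def test_identity_for_identical_sets(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        tf = kabsch(pts, pts)
        np.testing.assert_allclose(tf.matrix(), np.eye(4), atol=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 3))
        truth = RigidTransform.from_axis_angle((0, 0, 1), 30.0, (1, 2, 3))
        rec = kabsch(pts, truth.apply(pts))
        np.testing.assert_allclose(rec.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(rec.translation, truth.translation, atol=1e-9)

    def test_reflection_prevented_and_matches_sign_search(self):
        # a mirrored target makes the unconstrained optimum a reflection
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 3)) * np.array([1.0, 0.5, 0.1])
        tgt = pts * np.array([1.0, 1.0, -1.0])
        rec = kabsch(pts, tgt)
        assert np.linalg.det(rec.rotation) == pytest.approx(1.0, abs=1e-9)

        # oracle: brute-force search over sign corrections of the SVD
        src_c, tgt_c = pts.mean(0), tgt.mean(0)
        h = (pts - src_c).T @ (tgt - tgt_c)
        u, _, vt = np.linalg.svd(h)
        best = np.inf
        for signs in [(1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]:
            r = vt.T @ np.diag(signs) @ u.T
            if np.linalg.det(r) < 0:
                continue
            resid = np.sum(((pts - src_c) @ r.T - (tgt - tgt_c)) ** 2)
            best = min(best, resid)
        resid_rec = np.sum(((pts - src_c) @ rec.rotation.T - (tgt - tgt_c)) ** 2)
        np.testing.assert_allclose(resid_rec, best, rtol=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch(line, line)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestApplyTransform:
    def test_identity_is_bitwise(self, ellipsoid):
        out = apply_transform(ellipsoid, RigidTransform.identity())
        np.testing.assert_array_equal(out.vertices, ellipsoid.vertices)

    def test_transform_then_inverse(self, ellipsoid):
        tf = RigidTransform.from_axis_angle((1, 0, 1), 25.0, (0.4, 0.1, -0.3))
        back = apply_transform(apply_transform(ellipsoid, tf), tf.inverse())
        np.testing.assert_allclose(back.vertices, ellipsoid.vertices, atol=1e-9)

    def test_volume_invariant_under_rigid_motion(self, ellipsoid):
        tf = RigidTransform.from_axis_angle((2, 1, 0), 65.0, (5.0, -3.0, 1.0))
        v0 = mesh_volume(ellipsoid)
        v1 = mesh_volume(apply_transform(ellipsoid, tf))
        np.testing.assert_allclose(v1, v0, rtol=1e-9)


class TestIcpRegister:
    def test_identical_meshes_identity(self, ellipsoid):
        res = icp_register(
            ellipsoid, ellipsoid, IcpParams(initial_alignment="none", seed=0)
        )
        assert res.converged
        assert res.rms_trace[0] < 1e-9
        np.testing.assert_allclose(res.transform.matrix(), np.eye(4), atol=1e-9)

    def test_perturbation_recovery_on_asymmetric_shape(self, ellipsoid):
        moved, tf = apply_rigid_perturbation(
            ellipsoid, 5.0, axis=None, translation=(0.1, 0.07, -0.05), seed=3
        )
        res = icp_register(
            moved, ellipsoid, IcpParams(seed=1, max_iterations=500)
        )
        inv = tf.inverse()
        assert np.linalg.norm(res.transform.rotation - inv.rotation) < 1e-3
        assert np.linalg.norm(res.transform.translation - inv.translation) < 1e-3

    def test_rms_trace_monotone_nonincreasing(self, ellipsoid):
        moved, _ = apply_rigid_perturbation(
            ellipsoid, 8.0, axis=None, translation=(0.2, 0.0, 0.1), seed=9
        )
        res = icp_register(moved, ellipsoid, IcpParams(seed=2, max_iterations=50))
        diffs = np.diff(res.rms_trace[1:])
        assert (diffs <= 1e-12).all()

    def test_centroid_start_handles_large_displacement(self, ellipsoid):
        diameter = ellipsoid.bbox_diagonal()
        moved = apply_transform(
            ellipsoid,
            RigidTransform(np.eye(3), np.array([10.0, -4.0, 7.0]) * diameter),
        )
        res = icp_register(moved, ellipsoid, IcpParams(seed=0))
        assert res.rms_trace[-1] < 0.01 * diameter

    def test_translation_equivariance_with_centroid_start(self, ellipsoid):
        moved, _ = apply_rigid_perturbation(
            ellipsoid, 4.0, axis=None, translation=(0.05, 0.02, 0.0), seed=6
        )
        params = IcpParams(seed=4, max_iterations=20)
        base = icp_register(moved, ellipsoid, params)
        shift = RigidTransform(np.eye(3), np.array([3.0, -1.0, 2.0]))
        shifted = icp_register(apply_transform(moved, shift), ellipsoid, params)
        # centroid initialisation absorbs the shift: same correspondences,
        # result composed with the inverse shift
        np.testing.assert_allclose(
            shifted.transform.compose(shift).matrix(),
            base.transform.matrix(),
            atol=1e-9,
        )

    def test_seeded_sampling_is_deterministic(self, ellipsoid):
        moved, _ = apply_rigid_perturbation(ellipsoid, 6.0, seed=2)
        params = IcpParams(seed=7, n_sample_points=200, max_iterations=10)
        a = icp_register(moved, ellipsoid, params)
        b = icp_register(moved, ellipsoid, params)
        np.testing.assert_array_equal(a.transform.matrix(), b.transform.matrix())

    def test_non_convergence_reported_not_raised(self, ellipsoid):
        moved, _ = apply_rigid_perturbation(ellipsoid, 9.0, seed=1)
        res = icp_register(moved, ellipsoid, IcpParams(max_iterations=1))
        assert not res.converged
        assert res.n_iterations == 1

    def test_empty_mesh_rejected(self, ellipsoid):
        from endodisp import TriangleMesh

        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            icp_register(empty, ellipsoid)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            IcpParams(max_iterations=0)
        with pytest.raises(ValueError):
            IcpParams(trim_fraction=0.5)
        with pytest.raises(ValueError):
            IcpParams(n_sample_points=3)
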