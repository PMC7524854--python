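import numpy as np
import pytest

from lapreg.cloud import LabeledPointCloud
from lapreg.errors import (
    DegenerateFitError,
    InvalidPoseError,
    NoCorrespondenceError,
    RegistrationFailureError,
)
from lapreg.icp import (
    ICPParams,
    icp_register,
    kabsch_fit,
    manual_init,
    nearest_correspondences,
)
from lapreg.transforms import PointSet, RigidTransform, pose_difference

from .conftest import random_rigid_transform


class TestKabsch:
    def test_identity_when_target_equals_source(self, rng):
        P = PointSet(rng.normal(size=(30, 3)))
        assert kabsch_fit(P, P).is_close(RigidTransform.identity(), atol=1e-12)

    def test_recovers_random_rigid_transform(self, rng):
        for _ in range(10):
            T = random_rigid_transform(rng)
            src = rng.normal(scale=30, size=(50, 3))
            fit = kabsch_fit(PointSet(src), PointSet(T.apply(src)))
            assert fit.is_close(T, atol=1e-9)

    def test_weighted_fit_ignores_zero_weight_outlier(self, rng):
        T = random_rigid_transform(rng)
        src = rng.normal(scale=30, size=(20, 3))
        tgt = T.apply(src)
        src_o = np.vstack([src, [500.0, 0.0, 0.0]])
        tgt_o = np.vstack([tgt, [-500.0, 0.0, 0.0]])
        w = np.append(np.ones(20), 0.0)
        fit = kabsch_fit(PointSet(src_o, weights=w), PointSet(tgt_o))
        assert fit.is_close(T, atol=1e-9)

    def test_collinear_source_degenerate(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateFitError):
            kabsch_fit(PointSet(src), PointSet(src + 1.0))

    def test_too_few_points(self, rng):
        P = PointSet(rng.normal(size=(2, 3)))
        with pytest.raises(DegenerateFitError):
            kabsch_fit(P, P)

    def test_no_reflection_on_planar_data(self, rng):
        # planar source with a mirrored target must still return det +1
        src = np.column_stack([rng.normal(size=(20, 2)), np.zeros(20)])
        tgt = src * np.array([1.0, -1.0, 1.0])
        fit = kabsch_fit(PointSet(src), PointSet(tgt))
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)


class TestNearestCorrespondences:
    def test_self_pairing_at_zero_distance(self, rng):
        model = PointSet(rng.normal(scale=20, size=(100, 3)))
        src = PointSet(model.points[10:30])
        s, m, idx, d = nearest_correspondences(src, model, max_dist_mm=1.0)
        np.testing.assert_array_equal(idx, np.arange(10, 30))
        assert d.max() == 0.0

    def test_disjoint_sets_with_zero_threshold(self, rng):
        a = PointSet(rng.normal(size=(10, 3)))
        b = PointSet(rng.normal(size=(10, 3)) + 100.0)
        with pytest.raises(NoCorrespondenceError):
            nearest_correspondences(a, b, max_dist_mm=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        src = PointSet(rng.normal(scale=30, size=(100, 3)))
        model = PointSet(rng.normal(scale=30, size=(1000, 3)))
        s, m, idx, d = nearest_correspondences(src, model, max_dist_mm=np.inf)
        # oracle: exhaustive O(N*M) search
        diff = src.points[:, None, :] - model.points[None, :, :]
        d2 = np.einsum("nmk,nmk->nm", diff, diff)
        np.testing.assert_array_equal(idx, np.argmin(d2, axis=1))
        np.testing.assert_allclose(d, np.sqrt(d2.min(axis=1)), atol=1e-12)

    def test_threshold_discards_far_pairs(self, rng):
        src = PointSet(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        model = PointSet(np.array([[0.5, 0, 0]]))
        s, m, idx, d = nearest_correspondences(src, model, max_dist_mm=1.0)
        assert len(s) == 1 and d[0] == pytest.approx(0.5)


class TestManualInit:
    def test_zero_inputs_give_identity(self):
        assert manual_init().is_close(RigidTransform.identity())

    def test_translation_only(self):
        T = manual_init((1.0, 2.0, 3.0))
        np.testing.assert_array_equal(T.translation, [1, 2, 3])
        np.testing.assert_array_equal(T.rotation, np.eye(3))

    def test_euler_and_matrix_inputs_agree(self):
        T1 = manual_init((0, 0, 0), (10.0, 20.0, 30.0))
        T2 = manual_init((0, 0, 0), RigidTransform.from_euler_deg(10, 20, 30).rotation)
        assert T1.is_close(T2, atol=1e-12)

    def test_manual_mode_is_passthrough(self):
        # manual registration contract: the supplied pose IS the result
        T = manual_init((5.0, -2.0, 1.0), (1.0, 2.0, 3.0))
        assert T.is_close(manual_init((5.0, -2.0, 1.0), (1.0, 2.0, 3.0)))

    def test_invalid_rotation_rejected(self):
        with pytest.raises(InvalidPoseError):
            manual_init((0, 0, 0), np.ones((2, 2)))
        with pytest.raises(InvalidPoseError):
            manual_init((0, 0, np.nan))


class TestICPRegister:
    def test_fixed_point_at_identity(self, plain_scene, rng):
        # on-surface source at the true pose with identity-relative init:
        # first iteration is already optimal
        mesh = plain_scene.liver_mesh
        src = mesh.sample_surface(500, rng)
        cloud = LabeledPointCloud(src, np.zeros(500, dtype=np.int64))
        res = icp_register(cloud, mesh, RigidTransform.identity(),
                          ICPParams(model_sample_count=4000))
        assert res.inlier_rms_mm < 1e-6
        assert res.iterations_used <= 2
        assert res.converged

    def test_ground_truth_recovery(self, plain_scene, plain_cloud):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        perturb = RigidTransform(
            Rotation.from_rotvec(np.radians(5.0) * axis).as_matrix(),
            np.array([6.0, -5.0, 6.0]),
        )
        init = perturb.compose(plain_scene.true_pose)
        res = icp_register(
            plain_cloud, plain_scene.liver_mesh, init,
            ICPParams(model_sample_count=6000, convergence_tol_mm=1e-6,
                      max_iterations=400),
        )
        centroid = plain_scene.liver_mesh.vertices.mean(axis=0)
        t_err, r_err = pose_difference(res.transform, plain_scene.true_pose, centroid)
        assert t_err < 0.1
        assert r_err < 0.1

    def test_history_non_increasing(self, plain_scene, plain_cloud):
        init = RigidTransform(np.eye(3), np.array([10.0, 0.0, 0.0])).compose(
            plain_scene.true_pose
        )
        res = icp_register(plain_cloud, plain_scene.liver_mesh, init,
                          ICPParams(model_sample_count=6000, convergence_tol_mm=1e-5,
                                    max_iterations=300))
        assert np.all(np.diff(res.history) <= 1e-9)

    def test_far_init_raises_failure(self, plain_scene, plain_cloud):
        init = RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        with pytest.raises((RegistrationFailureError, NoCorrespondenceError)):
            icp_register(plain_cloud, plain_scene.liver_mesh, init,
                         ICPParams(model_sample_count=4000, failure_rms_mm=20.0,
                                   max_iterations=40))

    def test_failure_carries_partial_result(self, plain_scene, plain_cloud):
        init = RigidTransform(np.eye(3), np.array([200.0, 0.0, 0.0]))
        try:
            icp_register(plain_cloud, plain_scene.liver_mesh, init,
                         ICPParams(model_sample_count=4000, failure_rms_mm=20.0,
                                   max_correspondence_dist_mm=500.0,
                                   max_iterations=30))
        except RegistrationFailureError as e:
            assert e.result is not None
            assert len(e.result.history) == e.result.iterations_used
        else:  # pragma: no cover
            pytest.fail("expected a registration failure")

    def test_empty_cloud_rejected(self, plain_scene):
        cloud = LabeledPointCloud(np.empty((0, 3)), np.empty(0, dtype=np.int64))
        with pytest.raises(NoCorrespondenceError):
            icp_register(cloud, plain_scene.liver_mesh)

    def test_locator_matches_exact_closest_points(self, plain_scene, rng):
        # accelerated closest-point search vs brute force over all faces
        from lapreg.icp import _SurfaceLocator

        mesh = plain_scene.liver_mesh
        loc = _SurfaceLocator(mesh, 6000, np.random.default_rng(1))
        queries = mesh.sample_surface(150, rng) + rng.normal(scale=4.0, size=(150, 3))
        closest, dist = loc.closest(queries)
        _, exact_d, _ = mesh.closest_points(queries)
        np.testing.assert_allclose(dist, exact_d, atol=1e-9)

    def test_capture_range(self, plain_scene, plain_cloud):
        """Converges to < 1 mm pose error for offsets up to 20 mm."""
        centroid = plain_scene.liver_mesh.vertices.mean(axis=0)
        for offset in (10.0, 20.0):
            init = RigidTransform(np.eye(3), np.array([offset, 0.0, 0.0])).compose(
                plain_scene.true_pose
            )
            res = icp_register(plain_cloud, plain_scene.liver_mesh, init,
                              ICPParams(model_sample_count=6000,
                                        convergence_tol_mm=1e-5,
                                        max_iterations=300))
            t_err, _ = pose_difference(res.transform, plain_scene.true_pose, centroid)
            assert t_err < 1.0, f"offset {offset} mm: pose error {t_err:.2f} mm"


class TestICPParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ICPParams(max_iterations=0)
        with pytest.raises(ValueError):
            ICPParams(convergence_tol_mm=0.0)

    def test_dict_round_trip(self):
        p = ICPParams(max_iterations=7, failure_rms_mm=9.0)
        assert ICPParams.from_dict(p.to_dict()) == p
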