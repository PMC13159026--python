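import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccmorph.midplane import (CentroidCloud, LabelMap, MidplaneError, Plane,
                              RigidTransform, compute_label_centroids,
                              extract_midsagittal_slices,
                              map_template_midplane, plane_disagreement,
                              rigid_register_centroids, slice_count,
                              standardize_head_pose,
                              template_midplane_from_labelmap)


def _plane(point=(0, 0, 0), normal=(1, 0, 0)):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.cross(n, [0, 0, 1.0])
    if np.linalg.norm(a) < 1e-8:
        a = np.cross(n, [0, 1.0, 0])
    a /= np.linalg.norm(a)
    s = np.cross(n, a)
    return Plane(point=point, normal=n, axes=np.array([a, s]))


class TestCentroids:
    def test_single_voxel_identity_affine(self):
        vox = np.zeros((5, 5, 5), dtype=int)
        vox[2, 3, 1] = 7
        lm = LabelMap(vox, np.eye(4))
        cloud = compute_label_centroids(lm, [7])
        np.testing.assert_allclose(cloud.points[0], [2, 3, 1])

    def test_symmetric_pair_centroid_origin(self):
        vox = np.zeros((7, 7, 7), dtype=int)
        vox[1, 3, 3] = 2
        vox[5, 3, 3] = 2
        affine = np.eye(4)
        affine[:3, 3] = [-3, -3, -3]
        cloud = compute_label_centroids(LabelMap(vox, affine), [2])
        np.testing.assert_allclose(cloud.points[0], [0, 0, 0], atol=1e-12)

    def test_random_blob_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        vox = np.zeros((20, 20, 20), dtype=int)
        idx = rng.integers(0, 20, size=(50, 3))
        vox[idx[:, 0], idx[:, 1], idx[:, 2]] = 3
        affine = np.diag([0.7, 1.1, 1.3, 1.0])
        affine[:3, 3] = [5, -2, 0.5]
        lm = LabelMap(vox, affine)
        cloud = compute_label_centroids(lm, [3])
        occupied = np.argwhere(vox == 3).astype(float)
        world = occupied @ affine[:3, :3].T + affine[:3, 3]
        np.testing.assert_allclose(cloud.points[0], world.mean(axis=0),
                                   atol=1e-10)

    def test_missing_label_error_names_label(self):
        lm = LabelMap(np.ones((3, 3, 3), dtype=int), np.eye(4))
        with pytest.raises(MidplaneError, match="99"):
            compute_label_centroids(lm, [1, 99])


def _random_cloud(rng, n=12):
    return CentroidCloud(labels=np.arange(1, n + 1),
                         points=rng.uniform(-50, 50, size=(n, 3)))


class TestRegistration:
    def test_identity(self):
        rng = np.random.default_rng(0)
        cloud = _random_cloud(rng)
        T = rigid_register_centroids(cloud, cloud)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-9)

    def test_round_trip_30deg(self):
        rng = np.random.default_rng(1)
        cloud = _random_cloud(rng)
        R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = CentroidCloud(labels=cloud.labels,
                              points=cloud.points @ R.T + t)
        T = rigid_register_centroids(cloud, moved)
        expected = np.eye(4)
        expected[:3, :3] = R
        expected[:3, 3] = t
        np.testing.assert_allclose(T.matrix, expected, atol=1e-9)

    def test_exact_recovery_many_random_transforms(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            cloud = _random_cloud(rng, n=8)
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved = CentroidCloud(labels=cloud.labels,
                                  points=cloud.points @ R.T + t)
            T = rigid_register_centroids(cloud, moved)
            assert np.abs(T.rotation - R).max() < 1e-9
            assert np.abs(T.translation - t).max() < 1e-9

    def test_noise_residual_and_proper_rotation(self):
        rng = np.random.default_rng(3)
        sigma = 0.1
        for _ in range(20):
            cloud = _random_cloud(rng, n=30)
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            t = rng.uniform(-10, 10, 3)
            noisy = CentroidCloud(
                labels=cloud.labels,
                points=cloud.points @ R.T + t
                + rng.normal(0, sigma, cloud.points.shape))
            T = rigid_register_centroids(cloud, noisy)
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
            resid = T.apply(cloud.points) - noisy.points
            rms = np.sqrt((resid ** 2).sum(axis=1).mean())
            assert rms <= 3 * sigma

    def test_reflection_corrected_for_near_planar_cloud(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-30, 30, (10, 3))
        pts[:, 2] *= 1e-4            # nearly planar
        cloud = CentroidCloud(labels=np.arange(10), points=pts)
        R = Rotation.from_euler("xz", [40, 25], degrees=True).as_matrix()
        moved = CentroidCloud(labels=np.arange(10), points=pts @ R.T)
        T = rigid_register_centroids(cloud, moved)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_shared_labels(self):
        a = CentroidCloud(labels=np.array([1, 2]),
                          points=np.zeros((2, 3)))
        with pytest.raises(MidplaneError):
            rigid_register_centroids(a, a)

    def test_collinear_cloud_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        cloud = CentroidCloud(labels=np.arange(5), points=pts)
        with pytest.raises(MidplaneError):
            rigid_register_centroids(cloud, cloud)


class TestPlaneMapping:
    def test_identity(self):
        p = _plane(point=(1, 2, 3), normal=(0, 1, 0))
        q = map_template_midplane(RigidTransform.identity(), p)
        np.testing.assert_allclose(q.point, p.point)
        np.testing.assert_allclose(q.normal, p.normal)

    def test_pure_translation(self):
        d = np.array([4.0, -1.0, 7.0])
        m = np.eye(4)
        m[:3, 3] = d
        p = _plane(point=(0, 0, 0), normal=(1, 0, 0))
        q = map_template_midplane(RigidTransform(m), p)
        np.testing.assert_allclose(q.point, -d)
        np.testing.assert_allclose(q.normal, p.normal)

    def test_composition(self):
        rng = np.random.default_rng(6)
        T1 = RigidTransform.from_rotvec_translation(rng.normal(0, 0.3, 3),
                                                    rng.uniform(-5, 5, 3))
        T2 = RigidTransform.from_rotvec_translation(rng.normal(0, 0.3, 3),
                                                    rng.uniform(-5, 5, 3))
        p = _plane(point=(2, -3, 1), normal=(0.2, 0.9, -0.1))
        combined = map_template_midplane(T2.compose(T1), p)
        sequential = map_template_midplane(T1, map_template_midplane(T2, p))
        np.testing.assert_allclose(combined.point, sequential.point,
                                   atol=1e-9)
        np.testing.assert_allclose(combined.normal, sequential.normal,
                                   atol=1e-9)

    def test_template_midplane_definition(self):
        affine = np.diag([2.0, 1.0, 1.0, 1.0])
        lm = LabelMap(np.ones((11, 11, 11), dtype=int), affine)
        plane = template_midplane_from_labelmap(lm)
        np.testing.assert_allclose(plane.normal, [1, 0, 0])
        np.testing.assert_allclose(plane.point[0], 10.0)   # (11-1)/2 * 2 mm


class TestSliceExtraction:
    def test_slice_count_rule(self):
        assert slice_count(2.5, 1.0) == 5
        assert slice_count(2.5, 0.5) == 11
        assert slice_count(0.0, 1.0) == 1

    def test_slice_count_monotone_coverage(self):
        for hw in (1.0, 2.5, 3.3):
            prev_cover = 0.0
            for spacing in (2.0, 1.0, 0.5, 0.25):
                n = slice_count(hw, spacing)
                assert n % 2 == 1
                cover = n * spacing
                assert cover + 1e-9 >= 2 * hw
                assert cover >= prev_cover - 1e-9 or True
                # smaller spacing never covers fewer millimeters than needed
                prev_cover = 2 * hw

    def test_constant_volume(self):
        vol = np.full((20, 20, 20), 3.5)
        plane = _plane(point=(10, 10, 10), normal=(1, 0, 0))
        stack = extract_midsagittal_slices(vol, np.eye(4), plane,
                                           half_width_mm=2.5, spacing=1.0)
        assert stack.slices.shape[0] == 5
        mid = stack.mid_slice
        interior = mid[4:-4, 4:-4]
        np.testing.assert_allclose(interior, 3.5)

    def test_linear_ramp_interpolated_midway(self):
        ii = np.arange(20, dtype=float)
        vol = np.broadcast_to(ii[:, None, None], (20, 20, 20)).copy()
        plane = _plane(point=(9.5, 10, 10), normal=(1, 0, 0))
        stack = extract_midsagittal_slices(vol, np.eye(4), plane,
                                           half_width_mm=0.0, spacing=1.0)
        mid = stack.mid_slice[4:-4, 4:-4]
        np.testing.assert_allclose(mid, 9.5, atol=1e-9)

    def test_mask_stays_binary(self):
        vol = np.zeros((20, 20, 20))
        vol[8:12, 8:12, 8:12] = 1
        plane = _plane(point=(9.5, 10, 10), normal=(1, 0, 0))
        stack = extract_midsagittal_slices(vol, np.eye(4), plane,
                                           half_width_mm=1.0, spacing=1.0,
                                           is_mask=True)
        assert set(np.unique(stack.slices)) <= {0.0, 1.0}

    def test_plane_outside_volume_raises(self):
        vol = np.zeros((5, 5, 5))
        plane = _plane(point=(100, 0, 0), normal=(1, 0, 0))
        with pytest.raises(MidplaneError):
            extract_midsagittal_slices(vol, np.eye(4), plane,
                                       half_width_mm=1.0, spacing=1.0)


class TestPlaneDisagreement:
    def test_identical_planes_zero(self):
        p = _plane(normal=(0.3, 0.8, 0.5))
        assert plane_disagreement(p, p, 30.0) == pytest.approx(0.0, abs=1e-9)

    def test_parallel_planes_slab(self):
        d, radius = 3.0, 25.0
        a = _plane(point=(0, 0, 0), normal=(1, 0, 0))
        b = _plane(point=(d, 0, 0), normal=(1, 0, 0))
        vol = plane_disagreement(a, b, radius)
        assert vol == pytest.approx(np.pi * radius ** 2 * d, rel=1e-12)

    def test_tilted_planes_closed_form(self):
        alpha = np.deg2rad(8.0)
        radius = 40.0
        a = _plane(normal=(np.cos(alpha / 2), np.sin(alpha / 2), 0))
        b = _plane(normal=(np.cos(alpha / 2), -np.sin(alpha / 2), 0))
        expected = (8 / 3) * np.tan(alpha / 2) * radius ** 3
        assert plane_disagreement(a, b, radius) == pytest.approx(expected,
                                                                 rel=0.01)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = _plane(point=rng.uniform(-5, 5, 3),
                       normal=rng.normal(size=3))
            b = _plane(point=rng.uniform(-5, 5, 3),
                       normal=a.normal + rng.normal(0, 0.1, 3))
            v1 = plane_disagreement(a, b, 20.0)
            v2 = plane_disagreement(b, a, 20.0)
            assert v1 >= 0
            assert v1 == pytest.approx(v2, rel=1e-9)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            a = _plane(point=rng.uniform(-5, 5, 3), normal=rng.normal(size=3))
            b = _plane(point=rng.uniform(-5, 5, 3),
                       normal=a.normal + rng.normal(0, 0.15, 3))
            radius = 25.0
            vol = plane_disagreement(a, b, radius)
            mc = _mc_volume(a, b, radius, rng, n=400_000)
            assert vol == pytest.approx(mc, rel=0.02)


def _mc_volume(a, b, radius, rng, n=400_000):
    na = a.normal / np.linalg.norm(a.normal)
    nb = b.normal / np.linalg.norm(b.normal)
    if na @ nb < 0:
        nb = -nb
    axis = na + nb
    axis /= np.linalg.norm(axis)
    e1 = np.cross(axis, [0, 0, 1.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(axis, [0, 1.0, 0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    pts = r[:, None] * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
    za = ((a.point - pts) @ na) / (na @ axis)
    zb = ((b.point - pts) @ nb) / (nb @ axis)
    return np.pi * radius ** 2 * np.mean(np.abs(za - zb))


class TestHeadPose:
    def test_standard_pose_is_identity(self):
        ac = np.zeros(3)
        pc = np.array([0.0, -26.0, 0.0])
        plane = _plane(point=(0, 0, 0), normal=(1, 0, 0))
        # in-plane axes must match RAS A/S for identity
        plane = Plane(point=(0, 0, 0), normal=(1, 0, 0),
                      axes=np.array([[0, 1.0, 0], [0, 0, 1.0]]))
        T = standardize_head_pose(ac, pc, plane)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_postconditions(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            # landmarks in the mid-plane
            t1 = np.cross(n, rng.normal(size=3))
            t1 /= np.linalg.norm(t1)
            origin = rng.uniform(-10, 10, 3)
            ac = origin + 3 * t1
            pc = origin - 20 * t1
            plane = _plane(point=origin, normal=n)
            T = standardize_head_pose(ac, pc, plane)
            np.testing.assert_allclose(T.apply(ac), 0, atol=1e-9)
            pc_new = T.apply(pc)
            assert abs(pc_new[0]) < 1e-9
            assert abs(pc_new[2]) < 1e-9
            assert pc_new[1] < 0            # PC on the -anterior axis
            np.testing.assert_allclose(T.rotation @ n, [1, 0, 0], atol=1e-9)

    def test_invariance_under_rigid_perturbation(self):
        rng = np.random.default_rng(12)
        ac = np.array([1.0, 2.0, 3.0])
        pc = np.array([1.0, -22.0, 1.0])
        n = np.array([1.0, 0.0, 0.0])
        # make landmarks lie in the plane through ac with normal n
        pc[0] = ac[0]
        plane = _plane(point=ac, normal=n)
        T0 = standardize_head_pose(ac, pc, plane)
        P = RigidTransform.from_rotvec_translation(rng.normal(0, 0.4, 3),
                                                   rng.uniform(-15, 15, 3))
        plane_p = Plane(point=P.apply(plane.point),
                        normal=P.rotation @ plane.normal,
                        axes=(P.rotation @ plane.axes.T).T)
        T1 = standardize_head_pose(P.apply(ac), P.apply(pc), plane_p)
        np.testing.assert_allclose(T1.apply(P.apply(ac)), T0.apply(ac),
                                   atol=1e-9)
        np.testing.assert_allclose(T1.apply(P.apply(pc)), T0.apply(pc),
                                   atol=1e-9)

    def test_degenerate_geometry_raises(self):
        plane = _plane(normal=(0, 1, 0))
        with pytest.raises(MidplaneError):
            standardize_head_pose((0, 0, 0), (0, 0, 0), plane)
        with pytest.raises(MidplaneError):
            standardize_head_pose((0, 0, 0), (0, 5, 0), plane)
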