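"""Otsu two-level thresholding, point-cloud PCA, and symmetry alignment."""

import numpy as np
import pytest

from headreg import (
    PhantomSpec,
    PointCloud,
    RegistrationParams,
    Volume,
    align_to_symmetry,
    extract_head_points,
    generate_head_phantom,
    otsu_two_level,
    principal_axes,
    symmetry_transform,
)
from headreg.transforms import _euler_zyx_matrix


def brute_force_otsu(hist):
    """Independent exhaustive search over all threshold pairs."""
    hist = np.asarray(hist, dtype=float)
    n = hist.size
    levels = np.arange(n, dtype=float)
    total_w = hist.sum()
    mu = (hist * levels).sum() / total_w
    best, best_pair = -np.inf, None
    for t1 in range(n - 2):
        for t2 in range(t1 + 1, n - 1):
            sigma = 0.0
            for lo, hi in ((0, t1 + 1), (t1 + 1, t2 + 1), (t2 + 1, n)):
                w = hist[lo:hi].sum()
                if w > 0:
                    m = (hist[lo:hi] * levels[lo:hi]).sum() / w
                    sigma += w * (m - mu) ** 2
            if sigma > best:
                best, best_pair = sigma, (t1, t2)
    return best_pair


class TestOtsuTwoLevel:
    def test_three_delta_spikes_separated(self):
        hist = np.zeros(128)
        hist[[10, 50, 90]] = 100
        t1, t2 = otsu_two_level(hist)
        assert 10 <= t1 < 50
        assert 50 <= t2 < 90

    @pytest.mark.parametrize("bins", [16, 32])
    def test_matches_brute_force_on_random_histograms(self, bins, rng):
        for _ in range(50):
            hist = rng.integers(0, 30, size=bins)
            while np.count_nonzero(hist) < 3:
                hist = rng.integers(0, 30, size=bins)
            assert otsu_two_level(hist) == brute_force_otsu(hist)

    def test_agrees_with_independent_image_implementation(self, rng):
        # cross-check against skimage's multi-Otsu on the same 3-mode data
        from skimage.filters import threshold_multiotsu

        data = np.concatenate(
            [rng.normal(30, 4, 400), rng.normal(120, 6, 400), rng.normal(210, 5, 400)]
        ).clip(0, 255)
        hist, edges = np.histogram(data, bins=256, range=(0, 256))
        t1, t2 = otsu_two_level(hist)
        ours = np.array([edges[t1 + 1], edges[t2 + 1]])
        theirs = threshold_multiotsu(data, classes=3, nbins=256)
        np.testing.assert_allclose(ours, theirs, atol=2.0)

    def test_single_occupied_bin_rejected(self):
        hist = np.zeros(32)
        hist[5] = 100
        with pytest.raises(ValueError):
            otsu_two_level(hist)


class TestExtractHeadPoints:
    def test_point_count_matches_ellipsoid_volume(self, noise_free_spec):
        _, ct = generate_head_phantom(noise_free_spec, seed=0)
        pc = extract_head_points(ct)
        a, b, c = noise_free_spec.semi_axes
        analytic = 4.0 / 3.0 * np.pi * a * b * c
        assert abs(pc.points.shape[0] - analytic) / analytic < 0.02

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            extract_head_points(Volume(np.zeros((8, 8, 8))))

    def test_intensity_shift_invariance(self, noise_free_spec):
        _, ct = generate_head_phantom(noise_free_spec, seed=0)
        shifted = ct.with_voxels(ct.voxels + 11.5)
        np.testing.assert_array_equal(
            extract_head_points(ct).points, extract_head_points(shifted).points
        )


def ellipsoid_cloud(rng, semi=(20.0, 12.0, 6.0), n=6000, R=None):
    # rejection-sample a solid ellipsoid, optionally rotated
    pts = rng.uniform(-1, 1, (3 * n, 3))
    pts = pts[np.sum(pts**2, axis=1) <= 1.0][:n] * np.asarray(semi)
    if R is not None:
        pts = pts @ np.asarray(R).T
    return PointCloud(pts)


class TestPrincipalAxes:
    def test_axis_aligned_cloud_recovers_coordinate_axes(self, rng):
        frame = principal_axes(ellipsoid_cloud(rng))
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            angle = np.rad2deg(np.arccos(np.clip(abs(frame.axes[i] @ e), -1, 1)))
            assert angle < 1.0

    def test_rotation_equivariance(self, rng):
        pc = ellipsoid_cloud(rng)
        R = _euler_zyx_matrix(10.0, -7.0, 25.0)
        frame0 = principal_axes(pc)
        frame1 = principal_axes(PointCloud(pc.points @ R.T))
        for i in range(3):
            # up to the per-axis sign convention
            dot = abs(frame1.axes[i] @ (R @ frame0.axes[i]))
            assert np.rad2deg(np.arccos(np.clip(dot, -1, 1))) < 1.0

    def test_variances_are_covariance_eigenvalues(self, rng):
        pc = ellipsoid_cloud(rng)
        frame = principal_axes(pc)
        evals = np.sort(np.linalg.eigvalsh(np.cov(pc.points, rowvar=False)))[::-1]
        np.testing.assert_allclose(frame.variances, evals, rtol=1e-12)

    def test_degenerate_cloud_flagged(self, rng):
        flat = rng.random((100, 3))
        flat[:, 2] = 0.5  # coplanar
        with pytest.raises(ValueError):
            principal_axes(PointCloud(flat))

    def test_right_handedness_and_orthonormality(self, rng):
        frame = principal_axes(ellipsoid_cloud(rng, R=_euler_zyx_matrix(5, 40, -60)))
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-12)


class TestSymmetryTransform:
    def test_cloud_in_symmetry_pose_near_identity(self, rng):
        pc = ellipsoid_cloud(rng)
        v = Volume(np.zeros((8, 8, 8)), origin=(-3.5, -3.5, -3.5))  # grid center at 0
        frame = principal_axes(pc)
        T = symmetry_transform(frame, v)
        assert np.abs(T.rotation - np.eye(3)).max() < 0.05
        assert np.linalg.norm(T.translation) < 0.5

    def test_transformed_cloud_centered_and_diagonal(self, rng):
        pc = ellipsoid_cloud(rng, R=_euler_zyx_matrix(12, -8, 30))
        v = Volume(np.zeros((16, 16, 16)), spacing=(2, 2, 2))
        frame = principal_axes(pc)
        mapped = symmetry_transform(frame, v).apply_points(pc.points)
        np.testing.assert_allclose(mapped.mean(axis=0), v.physical_center, atol=1e-9)
        cov = np.cov(mapped, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6 * cov.max()


class TestAlignToSymmetry:
    def test_phantom_in_pose_unchanged(self, noise_free_spec):
        _, ct = generate_head_phantom(noise_free_spec, seed=1)
        aligned, T = align_to_symmetry(ct)
        inter = np.logical_and(aligned.voxels > 0.1, ct.voxels > 0.1).sum()
        dsc = 2 * inter / ((aligned.voxels > 0.1).sum() + (ct.voxels > 0.1).sum())
        assert dsc > 0.98

    def test_rotated_phantom_realigned(self, noise_free_spec):
        import dataclasses as dc

        from headreg.transforms import rotation_angle_deg

        posed = dc.replace(noise_free_spec, pose=RegistrationParams(rz=12.0))
        _, ct_ref = generate_head_phantom(noise_free_spec, seed=1)
        _, ct_rot = generate_head_phantom(posed, seed=1)
        aligned, T = align_to_symmetry(ct_rot)
        # the 12-degree pose must be recovered to within a degree ...
        assert abs(rotation_angle_deg(T) - 12.0) < 1.0
        # ... and the realigned foreground matches the unrotated phantom up
        # to boundary discretization of the thin head
        a = aligned.voxels > 0.15
        b = ct_ref.voxels > 0.15
        dsc = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
        assert dsc > 0.95

    def test_double_application_near_identity(self, noise_free_spec):
        import dataclasses as dc

        from headreg.transforms import rotation_angle_deg

        posed = dc.replace(noise_free_spec, pose=RegistrationParams(ry=-6.0, rz=9.0, tx=2.0))
        _, ct = generate_head_phantom(posed, seed=3)
        aligned, _ = align_to_symmetry(ct)
        _, T2 = align_to_symmetry(aligned)
        assert rotation_angle_deg(T2) < 1.0
        assert np.linalg.norm(T2.translation) < 1.0

    def test_empty_foreground_propagates(self):
        with pytest.raises(ValueError):
            align_to_symmetry(Volume(np.zeros((8, 8, 8))))

    def test_prealigned_volumes_agree_for_any_pretransform(self, rng):
        # the property the ground-truth stage depends on, checked on a
        # thicker head so voxelization does not dominate the overlap
        import dataclasses as dc

        spec = PhantomSpec(dims=(64, 64, 32), semi_axes=(24.0, 18.0, 11.0), noise_sd=(0.0, 0.0))
        for trial in range(3):
            angles = rng.uniform(-15, 15, 3)
            posed = dc.replace(spec, pose=RegistrationParams(*angles, *rng.uniform(-3, 3, 3)))
            _, ct_ref = generate_head_phantom(spec, seed=5)
            _, ct_posed = generate_head_phantom(posed, seed=5)
            a0, _ = align_to_symmetry(ct_ref)
            a1, _ = align_to_symmetry(ct_posed)
            ma, mb = a0.voxels > 0.15, a1.voxels > 0.15
            dsc = 2 * np.logical_and(ma, mb).sum() / (ma.sum() + mb.sum())
            assert dsc > 0.95
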