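import numpy as np
import pytest

from phenocloud.core_io import PointCloud
from phenocloud.preprocess import (alignment_from_normal, apply_alignment,
                                   bilateral_smooth, fit_ground_plane,
                                   hcsf_ground_mask, hcsf_split, hsi_to_rgb,
                                   remove_statistical_outliers, rgb_to_hsi)
from reference_impls import brute_sor_mask


class TestGroundPlane:
    def test_recovers_horizontal_plane_among_clutter(self, rng):
        pts = np.vstack([
            np.column_stack([rng.uniform(-1, 1, (1000, 2)), np.zeros(1000)]),
            np.column_stack([rng.uniform(-1, 1, (100, 2)),
                             rng.uniform(0.1, 0.3, 100)]),
        ])
        plane = fit_ground_plane(PointCloud(points=pts), dist_tol=0.01, seed=0)
        assert np.abs(plane.coeffs - [0, 0, 1, 0]).max() <= 1e-6

    def test_sign_convention_for_offset_plane(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (200, 2)),
                               np.full(200, 0.02)])
        plane = fit_ground_plane(PointCloud(points=pts), dist_tol=0.005, seed=0)
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-9)
        assert plane.coeffs[3] == pytest.approx(-0.02, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ground_plane(PointCloud(points=np.zeros((2, 3))))

    def test_collinear_support(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ground_plane(PointCloud(points=pts), seed=0)

    def test_normal_oriented_toward_crop(self, rng):
        # crop below the plane: normal must flip to point at it
        pts = np.vstack([
            np.column_stack([rng.uniform(-1, 1, (500, 2)), np.zeros(500)]),
            np.column_stack([rng.uniform(-1, 1, (60, 2)),
                             rng.uniform(-0.3, -0.1, 60)]),
        ])
        plane = fit_ground_plane(PointCloud(points=pts), dist_tol=0.01, seed=0)
        assert plane.normal[2] < 0


class TestAlignment:
    def test_identity_when_already_aligned(self):
        t = alignment_from_normal([0, 0, 1])
        assert np.abs(t.matrix - np.eye(3)).max() <= 1e-12

    def test_x_axis_to_z(self):
        t = alignment_from_normal([1, 0, 0])
        assert np.abs(t.matrix @ [1, 0, 0] - [0, 0, 1]).max() <= 1e-12

    def test_antiparallel_branch(self):
        t = alignment_from_normal([0, 0, -1])
        assert np.abs(t.matrix @ [0, 0, -1] - [0, 0, 1]).max() <= 1e-12
        # half-turn: trace of a 180 degree rotation is -1
        assert np.trace(t.matrix) == pytest.approx(-1.0)

    def test_property_thousand_random_normals(self, rng):
        """||R n - t|| <= 1e-9 and R^T R = I to 1e-9 for random unit n."""
        for _ in range(1000):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            t = alignment_from_normal(n)
            assert np.linalg.norm(t.matrix @ n - [0, 0, 1]) <= 1e-9
            assert np.abs(t.matrix.T @ t.matrix - np.eye(3)).max() <= 1e-9

    def test_apply_alignment_levels_tilted_field(self, rng):
        tilt = alignment_from_normal([0, 0, 1], t=[np.sin(np.radians(10)), 0,
                                                   np.cos(np.radians(10))])
        ground = np.column_stack([rng.uniform(-1, 1, (800, 2)),
                                  rng.normal(0, 0.002, 800)])
        crop = np.column_stack([rng.uniform(-1, 1, (200, 2)),
                                rng.uniform(0.05, 0.3, 200)])
        cloud = PointCloud(points=np.vstack([ground, crop]) @ tilt.matrix.T)
        plane = fit_ground_plane(cloud, dist_tol=0.01, seed=0)
        aligned = apply_alignment(cloud, plane)
        z = aligned.points[plane.inlier_indices, 2]
        assert np.abs(z).max() <= 0.01 + 1e-9

    def test_apply_alignment_is_rigid(self, rng):
        cloud = PointCloud(points=rng.uniform(-1, 1, (60, 3)))
        plane = fit_ground_plane(
            PointCloud(points=np.column_stack([
                rng.uniform(-1, 1, (100, 2)), np.zeros(100)])), seed=0)
        out = apply_alignment(cloud, plane)
        d_in = np.linalg.norm(cloud.points[:30] - cloud.points[30:], axis=1)
        d_out = np.linalg.norm(out.points[:30] - out.points[30:], axis=1)
        assert np.abs(d_in - d_out).max() <= 1e-9

    def test_already_aligned_is_noop(self, rng):
        ground = np.column_stack([rng.uniform(-1, 1, (300, 2)), np.zeros(300)])
        cloud = PointCloud(points=ground)
        plane = fit_ground_plane(cloud, seed=0)
        out = apply_alignment(cloud, plane)
        assert np.abs(out.points - cloud.points).max() <= 1e-9


class TestStatisticalOutliers:
    def test_single_far_point_removed(self, rng):
        blob = rng.normal(0, 0.01, (1000, 3))
        pts = np.vstack([blob, [[1.0, 0, 0]]])
        out = remove_statistical_outliers(PointCloud(points=pts), k=10, std_mult=2.0)
        assert len(out) == 1000
        assert not np.any(np.all(out.points == [1.0, 0, 0], axis=1))

    def test_uniform_grid_mostly_kept(self):
        g = np.stack(np.meshgrid(*[np.arange(10.0)] * 3), -1).reshape(-1, 3)
        out = remove_statistical_outliers(PointCloud(points=g), k=10, std_mult=2.0)
        assert len(out) >= 0.99 * len(g)

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1, (200, 3))
        out = remove_statistical_outliers(PointCloud(points=pts), k=8, std_mult=2.0)
        expected = pts[brute_sor_mask(pts, k=8, std_mult=2.0)]
        assert np.array_equal(out.points, expected)

    def test_repeated_passes_stay_bounded(self, default_field, rng):
        """Gross outliers go in one pass, and re-running never cascades: each
        pass removes at most the Gaussian-tail share of the threshold."""
        cloud, _ = default_field
        outliers = rng.uniform(2, 3, (100, 3))
        dirty = cloud.with_(points=np.vstack([cloud.points, outliers]),
                            colors=np.vstack([cloud.colors,
                                              np.full((100, 3), 0.5)]),
                            labels=None)
        p1 = remove_statistical_outliers(dirty, k=20, std_mult=2.0)
        assert p1.points[:, 0].max() < 2.0      # injected outliers all gone
        p2 = remove_statistical_outliers(p1, k=20, std_mult=2.0)
        assert (len(p1) - len(p2)) / len(p1) <= 0.10

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            remove_statistical_outliers(PointCloud(points=np.zeros((5, 3))), k=5)


class TestBilateral:
    def test_plane_noise_reduced(self, rng):
        xy = rng.uniform(0, 0.5, (4000, 2))
        z = rng.normal(0, 0.002, 4000)
        cloud = PointCloud(points=np.column_stack([xy, z]))
        out = bilateral_smooth(cloud, sigma_s=0.01, sigma_r=0.005, k=20)
        assert len(out) == len(cloud)
        rms_before = np.sqrt((z ** 2).mean())
        rms_after = np.sqrt((out.points[:, 2] ** 2).mean())
        assert rms_after <= 0.7 * rms_before

    def test_noise_free_plane_unmoved(self, rng):
        xy = rng.uniform(0, 0.5, (2000, 2))
        cloud = PointCloud(points=np.column_stack([xy, np.zeros(2000)]))
        out = bilateral_smooth(cloud, k=20)
        assert np.abs(out.points - cloud.points).max() <= 1e-6

    def test_crease_preserved(self, rng):
        # right-angle dihedral: points on the crease must not be smeared
        n = 3000
        s = rng.uniform(0, 0.2, n)
        t = rng.uniform(0, 0.2, n)
        half = rng.random(n) < 0.5
        pts = np.where(half[:, None],
                       np.column_stack([s, t, np.zeros(n)]),
                       np.column_stack([np.zeros(n), t, s]))
        cloud = PointCloud(points=pts)
        out = bilateral_smooth(cloud, sigma_s=0.01, sigma_r=0.005, k=20)
        crease = (pts[:, 0] < 0.01) & (pts[:, 2] < 0.01)
        disp = np.linalg.norm(out.points[crease] - pts[crease], axis=1)
        assert disp.max() <= 0.005


class TestHsi:
    @pytest.mark.parametrize("rgb,expect_h", [
        ((1.0, 0.0, 0.0), 0.0),
        ((0.0, 1.0, 0.0), 120.0),
        ((0.0, 0.0, 1.0), 240.0),
    ])
    def test_pure_hues(self, rgb, expect_h):
        hsi = rgb_to_hsi(np.array([rgb]))
        assert hsi.h[0] == pytest.approx(expect_h, abs=1e-6)
        assert hsi.s[0] == pytest.approx(1.0)

    def test_gray_and_black_conventions(self):
        hsi = rgb_to_hsi(np.array([[0.5, 0.5, 0.5], [0.0, 0.0, 0.0]]))
        assert hsi.s[0] == pytest.approx(0.0)
        assert hsi.h[0] == 0.0
        assert hsi.i[0] == pytest.approx(0.5)
        assert hsi.h[1] == hsi.s[1] == hsi.i[1] == 0.0

    def test_inverse_roundtrip_in_gamut(self, rng):
        h = rng.uniform(0, 360, 500)
        s = rng.uniform(0.1, 0.7, 500)
        i = rng.uniform(0.1, 0.5, 500)
        back = rgb_to_hsi(hsi_to_rgb(h, s, i))
        dh = np.abs((back.h - h + 180) % 360 - 180)
        assert np.median(dh) <= 0.5
        assert np.abs(back.i - i).max() <= 0.05


class TestHcsf:
    def test_bare_plane_is_all_ground(self, rng):
        xy = rng.uniform(0, 1, (2000, 2))
        cloud = PointCloud(points=np.column_stack([xy, np.zeros(2000)]),
                           colors=np.full((2000, 3), [0.6, 0.45, 0.25]))
        gp, gs = hcsf_split(cloud)
        assert len(gp) == 0
        assert len(gs) == len(cloud)

    def test_elevated_green_point_is_plant(self, rng):
        xy = rng.uniform(0, 1, (2000, 2))
        pts = np.vstack([np.column_stack([xy, np.zeros(2000)]),
                         [[0.5, 0.5, 0.5]]])
        colors = np.vstack([np.full((2000, 3), [0.6, 0.45, 0.25]),
                            [[0.1, 0.7, 0.1]]])
        gp, gs = hcsf_split(PointCloud(points=pts, colors=colors))
        assert len(gp) == 1
        assert gp.points[0, 2] == pytest.approx(0.5)

    def test_partition_and_accuracy_on_synthetic_field(self, default_field):
        cloud, _ = default_field
        mask = hcsf_ground_mask(cloud)
        gp, gs = hcsf_split(cloud)
        assert len(gp) + len(gs) == len(cloud)          # exact partition
        truth_ground = cloud.labels == 0
        assert mask[truth_ground].mean() >= 0.98        # ground -> GS
        assert (~mask)[~truth_ground].mean() >= 0.98    # plants -> GP

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            hcsf_split(PointCloud(points=np.empty((0, 3))))
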