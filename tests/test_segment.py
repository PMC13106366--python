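import math

import numpy as np
import pytest

from phenocloud.core_io import PointCloud
from phenocloud.localize import locate_plants
from phenocloud.segment import (GrowthParams, InstanceLabeling,
                                estimate_normals_curvature,
                                grow_instances, make_constraint_region,
                                region_height, resolve_overlaps,
                                segment_population)
from reference_impls import reference_grow


def sphere_cloud(rng, radius=0.05, n=8000):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return PointCloud(points=radius * v), v


class TestNormalsCurvature:
    def test_plane_normals_and_zero_curvature(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, (2000, 2)), np.zeros(2000)])
        cloud = estimate_normals_curvature(PointCloud(points=pts), k=15)
        assert np.abs(np.abs(cloud.normals[:, 2]) - 1).max() <= 1e-6
        assert cloud.curvatures.max() <= 1e-9

    def test_sphere_normals_radial(self, rng):
        cloud, radial = sphere_cloud(rng)
        out = estimate_normals_curvature(cloud, k=30)
        cos = np.abs(np.einsum("ij,ij->i", out.normals, radial))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() <= 3.0

    def test_curvature_ordering(self, rng):
        plane = estimate_normals_curvature(PointCloud(points=np.column_stack(
            [rng.uniform(0, 1, (1500, 2)), np.zeros(1500)])), k=15)
        sphere = estimate_normals_curvature(sphere_cloud(rng)[0], k=15)
        blob = estimate_normals_curvature(
            PointCloud(points=rng.normal(0, 0.05, (1500, 3))), k=15)
        assert plane.curvatures.mean() < sphere.curvatures.mean() < blob.curvatures.mean()

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            estimate_normals_curvature(PointCloud(points=np.zeros((5, 3))), k=10)


class TestConstraintRegion:
    def test_region_height_max_inside_cylinder(self):
        cloud = PointCloud(points=[[0, 0, 0.1], [0.01, 0, 0.31], [0.1, 0, 0.4]])
        assert region_height(cloud, [0, 0, 0.06], d_cyl=0.03) == pytest.approx(0.31)

    def test_empty_cylinder_is_error(self):
        cloud = PointCloud(points=[[1, 1, 0.2]])
        with pytest.raises(ValueError, match="locator without plant"):
            region_height(cloud, [0, 0, 0.06], d_cyl=0.03)

    def test_synthetic_region_height_tracks_truth(self, default_field):
        cloud, truths = default_field
        gp = cloud.select(cloud.labels > 0)
        for t in truths:
            r_hk = region_height(gp, np.append(t.stem_base[:2], 0.06), d_cyl=0.03)
            assert t.height - 0.01 <= r_hk <= t.height + 0.015

    def test_base_radius_from_cone_angle(self):
        """r_k = R_hk tan(alpha): 0.30 m at the default 35 degrees -> 0.2101 m."""
        region = make_constraint_region([0, 0, 0.06], 0.30, alpha=35.0, z_min=0.0)
        assert region.r_k == pytest.approx(0.30 * math.tan(math.radians(35.0)))
        assert region.r_k == pytest.approx(0.2101, abs=2e-4)

    def test_small_alpha_collapses(self):
        region = make_constraint_region([0, 0, 0], 0.30, alpha=1e-6, z_min=0.0)
        assert region.r_k < 1e-8

    def test_membership_predicate(self):
        region = make_constraint_region([0, 0, 0.06], 0.30, alpha=35.0, z_min=0.01)
        assert region.contains(np.array([[0.20, 0.0, 0.05]]))[0]
        assert not region.contains(np.array([[0.20, 0.0, 0.001]]))[0]
        assert not region.contains(np.array([[0.25, 0.0, 0.05]]))[0]

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            make_constraint_region([0, 0, 0], 0.3, alpha=95.0, z_min=0.0)


def _prep(cloud, k=20):
    return estimate_normals_curvature(cloud, k=k)


class TestGrow:
    def test_gap_beyond_delta_unreachable(self, rng):
        # flat ribbon with a far lone point: the 0.1 m gap >> delta blocks it
        ribbon = np.column_stack([rng.uniform(0, 0.1, 300),
                                  rng.uniform(0, 0.02, 300),
                                  np.full(300, 0.03)])
        far = [[0.25, 0.01, 0.03]]
        pts = np.vstack([ribbon, far])
        cloud = _prep(PointCloud(points=pts), k=8)
        region = make_constraint_region([0.05, 0, 0.06], 0.5, alpha=45.0, z_min=0.0)
        lab = grow_instances(cloud, {1: np.array([0])}, {1: region},
                             GrowthParams(delta=0.015))
        assert lab.labels[300] == 0
        assert (lab.labels[:300] == 1).mean() > 0.99

    def test_disjoint_regions_never_contest(self, rng):
        a = rng.normal(0, 0.005, (100, 3)) + [0, 0, 0.05]
        b = rng.normal(0, 0.005, (100, 3)) + [1.0, 0, 0.05]
        cloud = _prep(PointCloud(points=np.vstack([a, b])), k=10)
        ra = make_constraint_region([0, 0, 0.05], 0.1, alpha=35.0, z_min=-1.0)
        rb = make_constraint_region([1.0, 0, 0.05], 0.1, alpha=35.0, z_min=-1.0)
        lab = grow_instances(cloud, {1: np.array([0]), 2: np.array([100])},
                             {1: ra, 2: rb}, GrowthParams())
        assert not lab.contested
        assert set(lab.labels[:100]) <= {0, 1}
        assert set(lab.labels[100:]) <= {0, 2}

    def test_single_plant_fully_recovered(self, single_plant_field):
        cloud, truths = single_plant_field
        gp = _prep(cloud.select(cloud.labels > 0))
        locators, _ = locate_plants(gp)
        lab = segment_population(gp, locators, GrowthParams())
        assert (lab.labels == 1).mean() >= 0.99
        # and no ground point was ever labeled: gp excludes ground by construction
        assert set(np.unique(lab.labels)) <= {0, 1}

    def test_empty_seed_rejected(self, rng):
        cloud = _prep(PointCloud(points=rng.normal(0, 0.01, (50, 3)) + [0, 0, 0.05]), k=10)
        region = make_constraint_region([0, 0, 0.05], 0.3, alpha=35.0, z_min=-1.0)
        with pytest.raises(ValueError, match="empty seed"):
            grow_instances(cloud, {1: np.array([], dtype=int)}, {1: region},
                           GrowthParams())


class TestResolve:
    def test_no_contested_is_identity(self, rng):
        cloud = _prep(PointCloud(points=rng.normal(0, 0.02, (100, 3))), k=10)
        lab = InstanceLabeling(labels=np.ones(100, dtype=np.int64))
        out = resolve_overlaps(cloud, lab, GrowthParams())
        assert np.array_equal(out.labels, lab.labels)

    def test_contested_point_goes_to_coplanar_plant(self, rng):
        """A point on plant 1's leaf plane (d=0) and 2 cm off plant 2's plane
        is assigned to plant 1 under gamma2 = 0.5 cm."""
        n = 150
        plane1 = np.column_stack([rng.uniform(0, 0.04, (n, 2)),
                                  np.zeros(n)])              # z = 0
        plane2 = np.column_stack([rng.uniform(0, 0.04, (n, 2)),
                                  np.full(n, 0.02)])          # z = 0.02
        q = np.array([[0.02, 0.02, 0.0]])                     # on plane 1
        pts = np.vstack([plane1, plane2, q])
        cloud = _prep(PointCloud(points=pts), k=10)
        labels = np.concatenate([np.ones(n), np.full(n, 2), [0]]).astype(np.int64)
        lab = InstanceLabeling(labels=labels, contested={2 * n: (1, 2)})
        out = resolve_overlaps(cloud, lab, GrowthParams())
        assert out.labels[2 * n] == 1
        assert not out.contested

    def test_unacceptable_candidates_leave_point_unassigned(self, rng):
        n = 100
        plane1 = np.column_stack([rng.uniform(0, 0.04, (n, 2)), np.zeros(n)])
        q = np.array([[0.02, 0.02, 0.03]])     # 3 cm off the only plane
        cloud = _prep(PointCloud(points=np.vstack([plane1, q])), k=10)
        lab = InstanceLabeling(labels=np.append(np.ones(n), 0).astype(np.int64),
                               contested={n: (1,)})
        out = resolve_overlaps(cloud, lab, GrowthParams())
        assert out.labels[n] == 0


class TestSegmentPopulation:
    def test_field_recovers_all_instances(self, default_field):
        cloud, truths = default_field
        gp = _prep(cloud.select(cloud.labels > 0))
        locators, _ = locate_plants(gp)
        lab = segment_population(gp, locators, GrowthParams())
        assert len(set(lab.labels) - {0}) == len(truths)

    def test_containment_and_partition(self, default_field):
        """Every labeled point lies inside its plant's constraint cylinder,
        labels are single-valued, and contested is empty at exit."""
        cloud, truths = default_field
        gp = _prep(cloud.select(cloud.labels > 0))
        locators, _ = locate_plants(gp)
        params = GrowthParams()
        lab = segment_population(gp, locators, params)
        assert not lab.contested
        z_min = gp.points[:, 2].min()
        for loc in locators:
            r_hk = region_height(gp, loc.a_pk, d_cyl=params.d_cyl)
            region = make_constraint_region(loc.a_pk, r_hk, params.alpha, z_min)
            mine = lab.labels == loc.plant_index
            assert region.contains(gp.points[mine]).all()

    def test_order_invariance(self, rng):
        from phenocloud.synthfield import FieldSpec, generate_field
        spec_cloud, truths = generate_field(FieldSpec(rows=1, cols=2, seed=9))
        gp_idx = np.nonzero(spec_cloud.labels > 0)[0]
        gp = _prep(spec_cloud.select(gp_idx))
        locators, _ = locate_plants(gp)
        base = segment_population(gp, locators, GrowthParams())

        perm = rng.permutation(len(gp))
        inv = np.argsort(perm)
        gp_perm = _prep(spec_cloud.select(gp_idx[perm]).with_(normals=None,
                                                              curvatures=None))
        locs_perm, _ = locate_plants(gp_perm)
        out = segment_population(gp_perm, locs_perm, GrowthParams())
        assert np.array_equal(out.labels[inv], base.labels)

    def test_delta_monotonicity_single_plant(self, single_plant_field):
        """With one plant, enlarging delta never decreases the number of
        labeled points (reachability is monotone in the link radius; with
        several plants the contested dynamics break strict monotonicity)."""
        cloud, _ = single_plant_field
        gp = _prep(cloud.select(cloud.labels > 0))
        locators, _ = locate_plants(gp)
        counts = []
        for delta in (0.010, 0.015, 0.022):
            lab = segment_population(gp, locators,
                                     GrowthParams(delta=delta))
            counts.append(int((lab.labels > 0).sum()))
        assert counts[0] <= counts[1] <= counts[2]

    def test_matches_rescan_reference_on_small_field(self):
        """Production grower equals an unoptimized reference that re-scans all
        points every round (labels and contested keys)."""
        from phenocloud.synthfield import FieldSpec, generate_field
        cloud, truths = generate_field(FieldSpec(rows=1, cols=2, seed=4,
                                                 points_per_plant=600,
                                                 ground_points=0))
        gp = _prep(cloud.select(cloud.labels > 0))
        locators, _ = locate_plants(gp)
        params = GrowthParams()
        z_min = gp.points[:, 2].min()
        seeds, regions = {}, {}
        for loc in locators:
            r_hk = region_height(gp, loc.a_pk, d_cyl=params.d_cyl)
            regions[loc.plant_index] = make_constraint_region(
                loc.a_pk, r_hk, params.alpha, z_min)
            seeds[loc.plant_index] = loc.seed_indices
        lab = grow_instances(gp, seeds, regions, params)
        ref_labels, ref_contested = reference_grow(
            gp.points, gp.normals, gp.curvatures, seeds, regions, params)
        assert np.array_equal(lab.labels, ref_labels)
        assert set(lab.contested) == set(ref_contested)
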