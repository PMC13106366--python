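"""Instance segmentation by dynamically constrained region growing.

Each plant grows from its stem-layer seed cluster inside a private cylindrical
constraint region whose radius scales with that plant's own measured height:
r_k = R_hk * tan(alpha), where R_hk is the maximum z inside a small cylinder
of radius d around the localization point and alpha is the canopy cone
half-angle.  A neighbor q joins plant k when all three predicates hold:

  distance      ||p - q|| < delta          (spatial continuity)
  normals       |n_p . n_q| >= tau_N       (same surface orientation)
  membership    q inside the plant's constraint cylinder

Growth proceeds in synchronized breadth-first rounds across all plants; a
point reached by two or more plants in the same sweep is *contested* and is
settled afterwards by local geometry: for each candidate plant, the normal-
consistent neighborhood of the point is fitted with a plane, and the point
goes to the plant whose leaf plane it lies on (smallest plane distance within
gamma_2, curvature within gamma_1 standard deviations of the neighborhood).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from .core_io import PointCloud
from .localize import PlantLocator
from .preprocess import estimate_normals

__all__ = [
    "ConstraintRegion", "GrowthParams", "InstanceLabeling",
    "estimate_normals_curvature", "region_height", "make_constraint_region",
    "grow_instances", "resolve_overlaps", "segment_population",
]


@dataclasses.dataclass
class ConstraintRegion:
    """Per-plant growth cylinder: axis through the locator, base radius
    r_k = r_hk * tan(alpha), floor at z_min."""

    a_pk: np.ndarray
    r_hk: float
    alpha: float          # degrees
    r_k: float
    z_min: float

    def __post_init__(self):
        self.a_pk = np.asarray(self.a_pk, dtype=np.float64).reshape(3)
        if abs(self.r_k - self.r_hk * math.tan(math.radians(self.alpha))) > 1e-9:
            raise ValueError("r_k must equal r_hk * tan(alpha)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        dx = pts[:, 0] - self.a_pk[0]
        dy = pts[:, 1] - self.a_pk[1]
        return (dx * dx + dy * dy <= self.r_k ** 2) & (pts[:, 2] >= self.z_min)


@dataclasses.dataclass
class GrowthParams:
    """Region-growing knobs (meters / degrees / cosines).

    Defaults are the calibrated field values for seedling-stage row crops:
    delta 1.5 cm (branch-diameter scale), tau_N 0.85, d_cyl 3 cm, alpha 35
    degrees, plus overlap-resolution settings R_loc 2 cm, gamma1 2.0,
    gamma2 0.5 cm and k=20 normal estimation.
    """

    delta: float = 0.015
    tau_n: float = 0.85
    d_cyl: float = 0.03
    alpha: float = 35.0
    r_loc: float = 0.02
    gamma1: float = 2.0
    gamma2: float = 0.005
    k_normals: int = 20
    #: curvature above which a point counts as quasi-linear (stem/petiole);
    #: the normal-coherence test is waived for links touching such points,
    #: since eigen-normals of thin tubular structures carry no orientation
    #: signal.  None applies the normal test everywhere.
    curv_gate: float | None = 0.10

    def __post_init__(self):
        if self.delta <= 0 or not (0 < self.tau_n <= 1):
            raise ValueError("need delta > 0 and 0 < tau_n <= 1")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("need gamma1 > 0 and gamma2 > 0")
        if not (0 < self.alpha < 90):
            raise ValueError("alpha must lie in (0, 90) degrees")


@dataclasses.dataclass
class InstanceLabeling:
    """Per-point labels (0 unassigned, k >= 1 plant k) plus the contested
    points mapped to the plants that reached them."""

    labels: np.ndarray
    contested: dict[int, tuple[int, ...]] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)


def estimate_normals_curvature(cloud: PointCloud, k: int = 20) -> PointCloud:
    """Attach unit normals and curvature (lambda_0 / sum lambda) from k-NN
    covariance eigen-decomposition.  Normals are unoriented."""
    if k < 3:
        raise ValueError("k must be at least 3")
    normals, curvature = estimate_normals(cloud.points, k=k)
    return cloud.with_(normals=normals, curvatures=curvature)


def region_height(gp: PointCloud, a_pk, d_cyl: float = 0.03) -> float:
    """Maximum z among points within horizontal distance ``d_cyl`` of the
    locator — the plant's measured region height R_hk."""
    a = np.asarray(a_pk, dtype=np.float64).reshape(3)
    d2 = ((gp.points[:, :2] - a[:2]) ** 2).sum(axis=1)
    mask = d2 <= d_cyl ** 2
    if not mask.any():
        raise ValueError("no points inside the locator cylinder (locator without plant)")
    return float(gp.points[mask, 2].max())


def make_constraint_region(a_pk, r_hk: float, alpha: float = 35.0,
                           z_min: float = 0.0) -> ConstraintRegion:
    if not (0 < alpha < 90):
        raise ValueError("alpha must lie in (0, 90) degrees")
    return ConstraintRegion(a_pk=np.asarray(a_pk, dtype=np.float64),
                            r_hk=float(r_hk), alpha=float(alpha),
                            r_k=float(r_hk) * math.tan(math.radians(alpha)),
                            z_min=float(z_min))


def _adjacency(points: np.ndarray, delta: float):
    """Strict-inequality fixed-radius neighbor lists (CSR arrays)."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(delta, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < delta]          # query_pairs uses <=; the predicate is <
    both = np.vstack([pairs, pairs[:, ::-1]]) if len(pairs) else np.empty((0, 2), dtype=np.int64)
    order = np.argsort(both[:, 0], kind="stable")
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=len(points))
    starts = np.concatenate([[0], np.cumsum(counts)])
    return both[:, 1].astype(np.int64), starts


def grow_instances(gp: PointCloud, seeds: dict[int, np.ndarray],
                   regions: dict[int, ConstraintRegion],
                   params: GrowthParams) -> InstanceLabeling:
    """Plant-synchronous breadth-first growth under the three predicates.

    All plants expand one ring per round; claims are reconciled after each
    round, so a point reachable by several plants in the same round becomes
    contested irrespective of plant ordering.  Contested points stop growing.
    """
    pts = gp.points
    normals = gp.normals
    if normals is None:
        raise ValueError("grow_instances needs normals (run estimate_normals_curvature)")
    n = len(pts)
    labels = np.zeros(n, dtype=np.int64)
    contested: dict[int, set] = {}

    plant_ids = sorted(seeds)
    member = {}
    for k in plant_ids:
        if len(np.atleast_1d(seeds[k])) == 0:
            raise ValueError(f"plant {k}: empty seed set")
        member[k] = regions[k].contains(pts)
        if not member[k][np.atleast_1d(seeds[k])].all():
            raise ValueError(f"plant {k}: seed points outside the constraint region")

    nbr, starts = _adjacency(pts, params.delta)
    frontier = {}
    for k in plant_ids:
        idx = np.unique(np.atleast_1d(seeds[k]).astype(np.int64))
        labels[idx] = k
        frontier[k] = idx

    while any(len(frontier[k]) for k in plant_ids):
        claims: dict[int, list] = {}
        for k in plant_ids:
            new_pts = set()
            for p in frontier[k]:
                qs = nbr[starts[p]:starts[p + 1]]
                if len(qs) == 0:
                    continue
                free = qs[(labels[qs] == 0)]
                if len(free) == 0:
                    continue
                free = free[member[k][free]]
                if len(free) == 0:
                    continue
                cos = np.abs(gp.normals[free] @ gp.normals[p])
                ok = cos >= params.tau_n
                if params.curv_gate is not None and gp.curvatures is not None:
                    ok |= (gp.curvatures[free] > params.curv_gate) | \
                        (gp.curvatures[p] > params.curv_gate)
                new_pts.update(free[ok].tolist())
            for q in new_pts:
                if q in contested:
                    contested[q].add(k)
                else:
                    claims.setdefault(q, []).append(k)
        next_frontier = {k: [] for k in plant_ids}
        for q, ks in claims.items():
            if len(ks) == 1:
                labels[q] = ks[0]
                next_frontier[ks[0]].append(q)
            else:
                contested[q] = set(ks)
        frontier = {k: np.array(next_frontier[k], dtype=np.int64) for k in plant_ids}

    return InstanceLabeling(
        labels=labels,
        contested={q: tuple(sorted(ks)) for q, ks in sorted(contested.items())})


def _fit_plane_lsq(points: np.ndarray):
    """Total-least-squares plane with one outlier-trimmed refit; returns unit
    normal and offset d of a x + b y + c z + d = 0.

    Rows are put in canonical (lexicographic) order first so the fit is
    invariant to permutations of the input cloud.
    """
    points = points[np.lexsort(points.T)]
    sub = points
    for _ in range(2):
        c = sub.mean(axis=0)
        _, s, vt = np.linalg.svd(sub - c, full_matrices=False)
        normal = vt[2]
        d = -normal @ c
        if len(sub) <= 4:
            break
        resid = np.abs(points @ normal + d)
        tol = max(3.0 * np.median(resid), 1e-6)
        keep = resid <= tol
        if keep.sum() < 3 or keep.all():
            break
        sub = points[keep]
    return normal, d


def resolve_overlaps(gp: PointCloud, labeling: InstanceLabeling,
                     params: GrowthParams) -> InstanceLabeling:
    """Assign each contested point by local leaf-plane geometry.

    For each candidate plant k: gather that plant's points within ``r_loc`` of
    the contested point, keep the normal-consistent ones, fit a plane, and
    accept k when the point lies within ``gamma2`` of the plane and its
    curvature is within ``gamma1`` standard deviations of the neighborhood
    mean.  The accepting plant with the smallest plane distance wins (ties to
    the smaller id); if no plant accepts, the point stays unassigned.

    Resolution runs in synchronized passes: every decision in a pass sees only
    the labels from the previous pass, and passes repeat until a fixpoint, so
    the outcome is independent of point ordering while points resolved early
    still lend support to their neighbors in later passes.
    """
    if not labeling.contested:
        return labeling
    if gp.normals is None or gp.curvatures is None:
        raise ValueError("resolve_overlaps needs normals and curvature")
    labels = labeling.labels.copy()
    tree = cKDTree(gp.points)
    pending = dict(labeling.contested)
    for _ in range(len(pending) + 1):          # fixpoint within <= n passes
        decided = {}
        for q, cand in pending.items():
            nq = gp.normals[q]
            neigh = np.array(tree.query_ball_point(gp.points[q], params.r_loc),
                             dtype=np.int64)
            best = (np.inf, 0)
            for k in cand:
                mine = neigh[labels[neigh] == k]
                if len(mine) == 0:
                    continue
                cos = np.abs(gp.normals[mine] @ nq)
                fkq = mine[cos >= params.tau_n]
                if len(fkq) < 3:
                    continue
                normal, d = _fit_plane_lsq(gp.points[fkq])
                dist = abs(gp.points[q] @ normal + d)
                curv = np.sort(gp.curvatures[fkq])   # order-canonical moments
                mu = curv.mean()
                sigma = curv.std()
                curv_ok = abs(gp.curvatures[q] - mu) <= params.gamma1 * max(sigma, 1e-12)
                if dist < params.gamma2 and curv_ok and dist < best[0]:
                    best = (dist, k)
            if best[1] != 0:
                decided[q] = best[1]
        if not decided:
            break
        for q, k in decided.items():
            labels[q] = k
            del pending[q]
    return InstanceLabeling(labels=labels, contested={})


def segment_population(gp: PointCloud, locators: list[PlantLocator],
                       params: GrowthParams = GrowthParams()) -> InstanceLabeling:
    """End-to-end segmentation: measure each plant's region height, build its
    constraint cylinder, grow all plants synchronously, resolve overlaps."""
    if not locators:
        raise ValueError("no locators")
    cloud = gp
    if cloud.normals is None or cloud.curvatures is None:
        cloud = estimate_normals_curvature(cloud, k=params.k_normals)
    z_min = float(cloud.points[:, 2].min())
    seeds, regions = {}, {}
    for loc in locators:
        if loc.seed_indices is None or len(loc.seed_indices) == 0:
            raise ValueError(f"plant {loc.plant_index}: locator has no seed points")
        r_hk = region_height(cloud, loc.a_pk, d_cyl=params.d_cyl)
        regions[loc.plant_index] = make_constraint_region(
            loc.a_pk, r_hk, alpha=params.alpha, z_min=z_min)
        seeds[loc.plant_index] = loc.seed_indices
    labeling = grow_instances(cloud, seeds, regions, params)
    return resolve_overlaps(cloud, labeling, params)
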