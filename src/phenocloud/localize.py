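"""Per-plant localization from a bare-stem height layer.

In seedling-stage row crops the canopies entangle but the main stems stay
laterally separated, so a thin height slab just above the ground (the plant
localization zone) contains one compact point cluster per stem.  Density
clustering of that slab yields the clusters; each cluster's horizontal mean,
pinned at the top of the slab, is the plant's persistent localization point
and registry identity.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import PointCloud

__all__ = [
    "HeightLayer", "RootCluster", "PlantLocator",
    "slice_layer", "auto_epsilon", "dbscan_clusters",
    "localization_points", "build_registry", "locate_plants",
]

#: Clusters smaller than this multiple of min_pts are discarded as weeds/noise.
WEED_GUARD_FACTOR = 2


@dataclasses.dataclass(frozen=True)
class HeightLayer:
    """Closed height interval [l_low, l_high] in meters above corrected ground."""

    l_low: float = 0.02
    l_high: float = 0.06

    def __post_init__(self):
        if not (0 <= self.l_low < self.l_high):
            raise ValueError("need 0 <= l_low < l_high")


@dataclasses.dataclass
class RootCluster:
    """A stem-layer density cluster; ``indices`` address the sliced layer's
    source cloud."""

    indices: np.ndarray
    k: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.k < 1:
            raise ValueError("cluster ids start at 1")


@dataclasses.dataclass
class PlantLocator:
    """Per-plant localization point (mean x, mean y, layer top) plus registry
    identity and the stem-layer seed points it was derived from."""

    a_pk: np.ndarray
    plant_index: int
    variety: str = ""
    plot: str = ""
    seed_indices: np.ndarray | None = None

    def __post_init__(self):
        self.a_pk = np.asarray(self.a_pk, dtype=np.float64).reshape(3)
        if self.seed_indices is not None:
            self.seed_indices = np.asarray(self.seed_indices, dtype=np.int64)


def slice_layer(gp: PointCloud, layer: HeightLayer) -> tuple[PointCloud, np.ndarray]:
    """Points with l_low <= z <= l_high plus their indices in ``gp``."""
    z = gp.points[:, 2]
    idx = np.nonzero((z >= layer.l_low) & (z <= layer.l_high))[0]
    return gp.select(idx), idx


def auto_epsilon(points: np.ndarray, min_pts: int, n_dims: int | None = None) -> float:
    """Density-derived DBSCAN radius for roughly uniform point sets:

        eps = (T * MinPts * Gamma(n/2 + 1) / (m * pi^(n/2)))^(1/n)

    with T the bounding-box volume over the first ``n_dims`` coordinates.
    This is the radius at which a ball holds MinPts points on average.
    """
    pts = np.asarray(points, dtype=np.float64)
    if n_dims is None:
        n_dims = pts.shape[1]
    pts = pts[:, :n_dims]
    m = len(pts)
    if m < min_pts:
        raise ValueError(f"need at least min_pts={min_pts} points, got {m}")
    extents = pts.max(axis=0) - pts.min(axis=0)
    t = float(np.prod(extents))
    if t <= 0:
        raise ValueError("zero-extent bounding box: volume T is zero")
    return float((t * min_pts * math.gamma(n_dims / 2 + 1)
                  / (m * math.pi ** (n_dims / 2))) ** (1.0 / n_dims))


def dbscan_clusters(points: np.ndarray, eps: float, min_pts: int,
                    n_dims: int = 3) -> tuple[list[RootCluster], np.ndarray]:
    """Deterministic DBSCAN: density-reachability clustering with border-point
    ties broken by lowest cluster id.

    Core points (>= ``min_pts`` neighbors within ``eps``, self included) are
    expanded in index order; border points attach to the first (lowest-id)
    cluster that reaches them.  Returns clusters (ids from 1) and noise indices.
    """
    pts = np.asarray(points, dtype=np.float64)[:, :n_dims]
    if eps <= 0 or min_pts < 1:
        raise ValueError("need eps > 0 and min_pts >= 1")
    n = len(pts)
    if n == 0:
        return [], np.empty(0, dtype=np.int64)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=eps)
    is_core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.zeros(n, dtype=np.int64)   # 0 = unvisited/noise
    next_id = 1
    for start in range(n):
        if labels[start] != 0 or not is_core[start]:
            continue
        labels[start] = next_id
        stack = [start]
        while stack:
            p = stack.pop()
            for q in neighbors[p]:
                if labels[q] == 0:
                    labels[q] = next_id
                    if is_core[q]:
                        stack.append(q)
        next_id += 1
    clusters = [RootCluster(indices=np.nonzero(labels == cid)[0], k=cid)
                for cid in range(1, next_id)]
    return clusters, np.nonzero(labels == 0)[0]


def localization_points(clusters, source: PointCloud, layer: HeightLayer,
                        variety: str = "", plot: str = "",
                        row_bin: float = 0.05) -> list[PlantLocator]:
    """One locator per cluster: (mean x, mean y, l_high).  Plant indices are
    assigned in row-major order of (y, x); y is quantized to ``row_bin`` so
    within-row planting jitter does not scramble the walking order."""
    if not clusters:
        raise ValueError("no clusters to localize")
    centers = []
    for cl in clusters:
        pts = source.points[cl.indices, :2]
        # canonical summation order: the mean (hence the locator) is invariant
        # to permutations of the input cloud
        pts = pts[np.lexsort(pts.T)]
        xy = pts.mean(axis=0)
        centers.append((xy[0], xy[1], cl))
    order = sorted(range(len(centers)),
                   key=lambda i: (round(centers[i][1] / row_bin), centers[i][0]))
    locators = []
    for rank, i in enumerate(order, start=1):
        x, y, cl = centers[i]
        locators.append(PlantLocator(
            a_pk=np.array([x, y, layer.l_high]), plant_index=rank,
            variety=variety, plot=plot, seed_indices=cl.indices))
    return locators


def build_registry(locators, variety: str | None = None,
                   plot: str | None = None) -> pd.DataFrame:
    """Registry table (variety, plot, plant_index, x, y, z); errors on
    duplicate locators (double detection)."""
    if not locators:
        raise ValueError("no locators")
    rows = []
    for loc in locators:
        rows.append({
            "variety": variety if variety is not None else loc.variety,
            "plot": plot if plot is not None else loc.plot,
            "plant_index": loc.plant_index,
            "x": loc.a_pk[0], "y": loc.a_pk[1], "z": loc.a_pk[2],
        })
    df = pd.DataFrame(rows).sort_values("plant_index", ignore_index=True)
    xyz = df[["x", "y", "z"]].to_numpy()
    if len(xyz) > 1:
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(1e-6)
        if pairs:
            raise ValueError(f"duplicate locators within 1e-6: {sorted(pairs)}")
    return df


def locate_plants(gp: PointCloud, layer: HeightLayer = HeightLayer(),
                  eps: float | None = 0.012, min_pts: int = 6,
                  projected: bool = False, variety: str = "",
                  plot: str = "") -> tuple[list[PlantLocator], pd.DataFrame]:
    """Slice the stem layer, cluster it, and build locators plus the registry.

    ``eps=None`` switches to the density-derived radius (:func:`auto_epsilon`);
    ``projected`` clusters on (x, y) only.  Clusters smaller than
    ``WEED_GUARD_FACTOR * min_pts`` are dropped as weeds/noise.  Locator seed
    indices address ``gp``.
    """
    sliced, src_idx = slice_layer(gp, layer)
    if len(sliced) == 0:
        raise ValueError("stem layer is empty: no plants found")
    n_dims = 2 if projected else 3
    if eps is None:
        eps = auto_epsilon(sliced.points, min_pts, n_dims=n_dims)
    clusters, _ = dbscan_clusters(sliced.points, eps=eps, min_pts=min_pts,
                                  n_dims=n_dims)
    clusters = [cl for cl in clusters if len(cl.indices) >= WEED_GUARD_FACTOR * min_pts]
    if not clusters:
        raise ValueError("no stem clusters above the weed guard")
    # re-index into the full gp cloud
    remapped = [RootCluster(indices=src_idx[cl.indices], k=i + 1)
                for i, cl in enumerate(clusters)]
    locators = localization_points(remapped, gp, layer, variety=variety, plot=plot)
    return locators, build_registry(locators)
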