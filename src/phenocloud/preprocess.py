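"""Region-of-interest cleanup for field scenes.

Order of operations on a raw reconstruction:

1. RANSAC ground-plane fit and quaternion alignment of the ground normal to
   +z, plus a translation putting the ground at z = 0 — all later heights are
   plain z-differences.
2. Statistical outlier removal and bilateral smoothing to strip reconstruction
   noise without shrinking thin organs.
3. A hue-aware cloth-simulation filter (HCSF) that splits the scene into
   ground-surface (GS) and ground-plant (GP) points: a virtual cloth settles
   onto the inverted cloud to model the terrain, points near the settled cloth
   are ground candidates, and candidates whose HSI hue falls in the vegetation
   band are vetoed back to the plant side so green stem bases are never lost
   to the terrain.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .core_io import PointCloud
from .splats import quat_to_matrix

__all__ = [
    "GroundPlane", "AlignmentTransform", "HsiColor",
    "fit_ground_plane", "alignment_from_normal", "apply_alignment",
    "remove_statistical_outliers", "bilateral_smooth",
    "rgb_to_hsi", "hsi_to_rgb", "hcsf_split", "estimate_normals",
]


@dataclasses.dataclass
class GroundPlane:
    """Plane ax + by + cz + d = 0 with unit normal (a, b, c) oriented toward
    the crop side (non-inliers have positive mean signed distance)."""

    coeffs: np.ndarray          # (4,) = (a, b, c, d)
    inlier_indices: np.ndarray  # points within the fit tolerance

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).reshape(4)
        nrm = np.linalg.norm(self.coeffs[:3])
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        self.inlier_indices = np.asarray(self.inlier_indices, dtype=np.int64)

    @property
    def normal(self) -> np.ndarray:
        return self.coeffs[:3]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return points @ self.coeffs[:3] + self.coeffs[3]


@dataclasses.dataclass
class AlignmentTransform:
    """Rotation taking the ground normal to the target axis, stored both as a
    unit quaternion (w, x, y, z) and the equivalent 3x3 matrix."""

    quat: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.quat = np.asarray(self.quat, dtype=np.float64).reshape(4)
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        if np.abs(self.matrix @ self.matrix.T - np.eye(3)).max() > 1e-9:
            raise ValueError("matrix must be orthonormal")
        if abs(np.linalg.det(self.matrix) - 1.0) > 1e-9:
            raise ValueError("matrix must be a proper rotation")


@dataclasses.dataclass
class HsiColor:
    """HSI channels as parallel arrays: hue in degrees [0, 360), saturation
    and intensity in [0, 1].  Gray inputs give s = 0 (and h = 0 by convention)."""

    h: np.ndarray
    s: np.ndarray
    i: np.ndarray


def _plane_from_points(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    nrm = np.linalg.norm(n)
    if nrm < 1e-12:
        return None
    n = n / nrm
    return np.append(n, -n @ p0)


def fit_ground_plane(cloud: PointCloud, dist_tol: float = 0.01,
                     iters: int = 200, seed: int = 0) -> GroundPlane:
    """RANSAC plane maximizing the inlier count at ``dist_tol``, refit by least
    squares on its inliers, normal oriented toward the off-plane points."""
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    best_count, best = -1, None
    for _ in range(iters):
        i, j, k = rng.choice(n, size=3, replace=False)
        cand = _plane_from_points(pts[i], pts[j], pts[k])
        if cand is None:
            continue
        count = int(np.count_nonzero(np.abs(pts @ cand[:3] + cand[3]) <= dist_tol))
        if count > best_count:
            best_count, best = count, cand
    if best is None:
        raise ValueError("degenerate support: points are collinear")

    # least-squares refit on inliers (smallest-eigenvector plane)
    for _ in range(2):
        inl = np.abs(pts @ best[:3] + best[3]) <= dist_tol
        sub = pts[inl]
        if len(sub) < 3:
            break
        c = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - c, full_matrices=False)
        normal = vt[2]
        best = np.append(normal, -normal @ c)

    inliers = np.nonzero(np.abs(pts @ best[:3] + best[3]) <= dist_tol)[0]
    outliers = np.setdiff1d(np.arange(n), inliers, assume_unique=True)
    if len(outliers) and (pts[outliers] @ best[:3] + best[3]).mean() < 0:
        best = -best
    elif not len(outliers) and best[2] < 0:   # bare plane: prefer +z
        best = -best
    return GroundPlane(coeffs=best, inlier_indices=inliers)


def alignment_from_normal(n: np.ndarray, t=(0.0, 0.0, 1.0)) -> AlignmentTransform:
    """Rotation taking unit vector ``n`` onto unit vector ``t``.

    Axis k = n x t / |n x t|, angle theta = arccos(n . t), quaternion
    q = (cos(theta/2), sin(theta/2) k).  When n is within machine precision of
    -t (axis undefined) the rotation is 180 degrees about a fixed axis
    perpendicular to t.
    """
    n = np.asarray(n, dtype=np.float64).reshape(3)
    t = np.asarray(t, dtype=np.float64).reshape(3)
    n = n / np.linalg.norm(n)
    t = t / np.linalg.norm(t)
    axis = np.cross(n, t)
    s = np.linalg.norm(axis)
    c = float(np.clip(n @ t, -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            quat = np.array([1.0, 0.0, 0.0, 0.0])
        else:
            # antiparallel: any axis perpendicular to t works; pick deterministically
            perp = np.cross(t, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(t, [0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            quat = np.concatenate([[0.0], perp])
    else:
        axis = axis / s
        theta = np.arccos(c)
        quat = np.concatenate([[np.cos(theta / 2)], np.sin(theta / 2) * axis])
    return AlignmentTransform(quat=quat, matrix=quat_to_matrix(quat))


def apply_alignment(cloud: PointCloud, plane: GroundPlane,
                    transform: AlignmentTransform | None = None) -> PointCloud:
    """Rotate the cloud so the ground normal becomes +z and translate so the
    rotated ground plane sits at z = 0.  Rigid: pairwise distances preserved."""
    if transform is None:
        n = plane.normal if plane.normal[2] >= 0 else -plane.normal
        transform = alignment_from_normal(n)
    r = transform.matrix
    p0 = -plane.coeffs[3] * plane.normal          # a point on the plane
    z_off = (r @ p0)[2]
    pts = cloud.points @ r.T
    pts[:, 2] -= z_off
    normals = None if cloud.normals is None else cloud.normals @ r.T
    return cloud.with_(points=pts, normals=normals)


def remove_statistical_outliers(cloud: PointCloud, k: int = 20,
                                std_mult: float = 2.0) -> PointCloud:
    """Drop points whose mean distance to their k nearest neighbors exceeds the
    global mean by more than ``std_mult`` standard deviations."""
    n = len(cloud)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count {n}")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=k + 1)   # first neighbor is the point itself
    mean_d = dist[:, 1:].mean(axis=1)
    keep = mean_d <= mean_d.mean() + std_mult * mean_d.std()
    return cloud.select(keep)


def estimate_normals(points: np.ndarray, k: int = 20):
    """Per-point unit normal and curvature from local covariance.

    Normal = eigenvector of the smallest eigenvalue over the k-NN covariance;
    curvature = lambda_0 / (lambda_0 + lambda_1 + lambda_2).  Normal signs are
    arbitrary (unoriented).
    """
    n = len(points)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    nbrs = points[idx]                               # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)               # ascending eigenvalues
    normals = evecs[:, :, 0]
    total = evals.sum(axis=1)
    curvature = np.where(total > 0, evals[:, 0] / np.where(total > 0, total, 1.0), 0.0)
    return normals, curvature


def bilateral_smooth(cloud: PointCloud, sigma_s: float = 0.01,
                     sigma_r: float = 0.005, k: int = 20) -> PointCloud:
    """Move each point along its normal by the bilaterally weighted mean of the
    normal offsets of its k nearest neighbors.

    The spatial kernel (sigma_s) limits influence to the local patch and the
    range kernel (sigma_r) down-weights neighbors far off the local surface, so
    creases and leaf edges are preserved while z-noise on laminae is damped.
    Point count is unchanged.
    """
    n = len(cloud)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points")
    normals = cloud.normals
    if normals is None:
        normals, _ = estimate_normals(cloud.points, k=k)
    tree = cKDTree(cloud.points)
    dist, idx = tree.query(cloud.points, k=k + 1)
    offsets = np.einsum("nj,nkj->nk", normals,
                        cloud.points[idx] - cloud.points[:, None, :])
    w = np.exp(-dist ** 2 / (2 * sigma_s ** 2)) * np.exp(-offsets ** 2 / (2 * sigma_r ** 2))
    disp = (w * offsets).sum(axis=1) / w.sum(axis=1)
    return cloud.with_(points=cloud.points + disp[:, None] * normals,
                       normals=cloud.normals)


def rgb_to_hsi(colors: np.ndarray) -> HsiColor:
    """Standard HSI conversion: I = (R+G+B)/3, S = 1 - 3 min/(R+G+B), and H
    from the arccos form, reflected to (180, 360) when B > G.  Black maps to
    (0, 0, 0) by convention."""
    c = np.atleast_2d(np.asarray(colors, dtype=np.float64))
    r, g, b = c[:, 0], c[:, 1], c[:, 2]
    total = r + g + b
    i = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * c.min(axis=1) / np.where(total > 0, total, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        h = np.degrees(np.arccos(np.clip(np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 1.0), -1.0, 1.0)))
    h = np.where(den <= 1e-12, 0.0, h)
    h = np.where(b > g, 360.0 - h, h) % 360.0
    return HsiColor(h=h, s=np.clip(s, 0.0, 1.0), i=i)


def hsi_to_rgb(h, s, i) -> np.ndarray:
    """Inverse HSI transform (sector form), used by the synthetic generator."""
    h = np.asarray(h, dtype=np.float64) % 360.0
    s = np.asarray(s, dtype=np.float64)
    i = np.asarray(i, dtype=np.float64)
    h, s, i = np.broadcast_arrays(h, s, i)
    rgb = np.empty(h.shape + (3,))
    # sector -> which of (i(1-s), i(1+...), remainder) feeds R, G, B
    for lo, order in ((0.0, (1, 2, 0)), (120.0, (0, 1, 2)), (240.0, (2, 0, 1))):
        sector = (h >= lo) & (h < lo + 120.0)
        hh = np.radians(h[sector] - lo)
        x = i[sector] * (1.0 - s[sector])
        y = i[sector] * (1.0 + s[sector] * np.cos(hh) / np.cos(np.radians(60.0) - hh))
        z = 3.0 * i[sector] - (x + y)
        vals = (x, y, z)
        for axis, src in enumerate(order):
            rgb[sector, axis] = vals[src]
    return np.clip(rgb, 0.0, 1.0)


def _simulate_cloth(points: np.ndarray, res: float, rigidness: int,
                    n_iter: int = 80):
    """Settle a virtual cloth onto the inverted cloud (z -> -z).

    Grid nodes fall under gravity, pin when they touch the inverted surface of
    their cell, and are pulled toward their neighbor mean ``rigidness`` times
    per step (cloth stiffness), so the cloth bridges over canopy pits and
    tracks only the terrain.  Returns the settled cloth height in the inverted
    frame plus the grid axes.
    """
    inv_z = -points[:, 2]
    x0, y0 = points[:, 0].min() - res, points[:, 1].min() - res
    nx = max(2, int(np.ceil((points[:, 0].max() + res - x0) / res)) + 1)
    ny = max(2, int(np.ceil((points[:, 1].max() + res - y0) / res)) + 1)
    xs = x0 + np.arange(nx) * res
    ys = y0 + np.arange(ny) * res

    ix = np.clip(np.round((points[:, 0] - x0) / res).astype(int), 0, nx - 1)
    iy = np.clip(np.round((points[:, 1] - y0) / res).astype(int), 0, ny - 1)
    target = np.full((nx, ny), -np.inf)
    np.maximum.at(target, (ix, iy), inv_z)

    finite = np.isfinite(target)
    h = np.full((nx, ny), inv_z.max() + 10 * res)
    pinned = np.zeros((nx, ny), dtype=bool)
    step = max(res, 1e-4)
    for _ in range(n_iter):
        h = np.where(pinned, h, h - step)
        for _ in range(max(1, rigidness)):
            pad = np.pad(h, 1, mode="edge")
            nb_mean = (pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:]) / 4.0
            h = np.where(pinned, h, 0.5 * (h + nb_mean))
        hit = finite & (h <= target)
        h = np.where(hit, target, h)
        pinned |= hit
    # unpinned nodes (cells with no terrain support) relax to a smooth
    # interpolation of the pinned cloth instead of keeping gravity sag
    for _ in range(200):
        pad = np.pad(h, 1, mode="edge")
        nb_mean = (pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:]) / 4.0
        new_h = np.where(pinned, h, nb_mean)
        if np.abs(new_h - h).max() < 1e-6:
            h = new_h
            break
        h = new_h
    return h, xs, ys


def hcsf_ground_mask(cloud: PointCloud, cloth_res: float = 0.02,
                     rigidness: int = 3, class_tol: float = 0.015,
                     hue_band: tuple = (60.0, 180.0),
                     sat_min: float = 0.1) -> np.ndarray:
    """Boolean mask of ground (GS) points under the hue-aware cloth filter."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    h, xs, ys = _simulate_cloth(cloud.points, cloth_res, rigidness)
    interp = RegularGridInterpolator((xs, ys), h, bounds_error=False, fill_value=None)
    cloth_at = interp(cloud.points[:, :2])
    ground_cand = np.abs(-cloud.points[:, 2] - cloth_at) <= class_tol

    hsi = rgb_to_hsi(cloud.colors)
    veg = (hsi.h >= hue_band[0]) & (hsi.h <= hue_band[1]) & (hsi.s > sat_min)
    return ground_cand & ~veg


def hcsf_split(cloud: PointCloud, cloth_res: float = 0.02, rigidness: int = 3,
               class_tol: float = 0.015, hue_band: tuple = (60.0, 180.0),
               sat_min: float = 0.1) -> tuple[PointCloud, PointCloud]:
    """Hue-aware cloth-simulation split into (GP plants, GS ground).

    Points within ``class_tol`` of the settled cloth are ground candidates;
    candidates whose hue lies in ``hue_band`` with saturation above
    ``sat_min`` are vetoed back to the plant side (green stem bases sit inside
    the terrain tolerance but are chromatically vegetation).  The two outputs
    partition the input exactly.
    """
    is_ground = hcsf_ground_mask(cloud, cloth_res, rigidness, class_tol,
                                 hue_band, sat_min)
    return cloud.select(~is_ground), cloud.select(is_ground)
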