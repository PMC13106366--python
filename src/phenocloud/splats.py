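"""Dense point sampling from a 3-D Gaussian-splat scene.

A trained splat scene represents the crop canopy as a set of anisotropic
Gaussians G(x) = exp(-1/2 (x-mu)^T Sigma^-1 (x-mu)) with covariance
Sigma = R S S^T R^T factored into a rotation R (from a unit quaternion) and a
diagonal scale matrix S of per-axis standard deviations.  To turn the scene
into a point cloud we draw points from each Gaussian in proportion to its
opacity and size, and reject improbable draws by a Mahalanobis-distance
threshold, so thin stems and leaf laminae stay crisp instead of being smeared
by low-probability tails.

The on-disk format is the community splat PLY dialect: per-vertex ``x,y,z``,
log-scales ``scale_0..2``, quaternion ``rot_0..3`` (w, x, y, z), logit
``opacity`` and band-0 spherical-harmonic color ``f_dc_0..2``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._ply import PlyError, read_ply
from .core_io import PointCloud

__all__ = ["GaussianPrimitive", "SplatSet", "load_splats", "sample_points",
           "quat_to_matrix", "SH_C0"]

#: Band-0 spherical-harmonic basis constant, 1 / (2 sqrt(pi)).
SH_C0 = 0.28209479177387814

#: Primitives with opacity below this contribute no samples (floater suppression).
MIN_OPACITY = 0.05


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of unit quaternion(s) ``(w, x, y, z)``.

    Accepts shape (4,) or (n, 4); returns (3, 3) or (n, 3, 3).
    """
    q = np.asarray(q, dtype=np.float64)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - z * w)
    m[:, 0, 2] = 2 * (x * z + y * w)
    m[:, 1, 0] = 2 * (x * y + z * w)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - x * w)
    m[:, 2, 0] = 2 * (x * z - y * w)
    m[:, 2, 1] = 2 * (y * z + x * w)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m[0] if single else m


@dataclasses.dataclass
class GaussianPrimitive:
    """One anisotropic Gaussian: center, orientation, per-axis sigma, opacity, RGB."""

    mu: np.ndarray
    rot: np.ndarray        # unit quaternion (w, x, y, z)
    scale: np.ndarray      # per-axis standard deviations, meters
    opacity: float
    color: np.ndarray      # RGB in [0, 1]

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).reshape(3)
        self.rot = np.asarray(self.rot, dtype=np.float64).reshape(4)
        nrm = np.linalg.norm(self.rot)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("quaternion must be finite and nonzero")
        self.rot = self.rot / nrm
        self.scale = np.asarray(self.scale, dtype=np.float64).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")
        self.opacity = float(self.opacity)
        self.color = np.clip(np.asarray(self.color, dtype=np.float64).reshape(3), 0, 1)

    @property
    def covariance(self) -> np.ndarray:
        """Sigma = R S S^T R^T."""
        r = quat_to_matrix(self.rot)
        return r @ np.diag(self.scale ** 2) @ r.T


@dataclasses.dataclass
class SplatSet:
    """A splat scene as parallel arrays (fast path) over all primitives."""

    mu: np.ndarray       # (n, 3)
    rot: np.ndarray      # (n, 4) unit quaternions (w, x, y, z)
    scale: np.ndarray    # (n, 3) sigmas
    opacity: np.ndarray  # (n,)
    color: np.ndarray    # (n, 3)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).reshape(-1, 3)
        n = len(self.mu)
        self.rot = np.asarray(self.rot, dtype=np.float64).reshape(n, 4)
        self.rot = self.rot / np.linalg.norm(self.rot, axis=1, keepdims=True)
        self.scale = np.asarray(self.scale, dtype=np.float64).reshape(n, 3)
        self.opacity = np.asarray(self.opacity, dtype=np.float64).reshape(n)
        self.color = np.clip(np.asarray(self.color, dtype=np.float64).reshape(n, 3), 0, 1)
        for name in ("mu", "rot", "scale", "opacity", "color"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")

    def __len__(self) -> int:
        return len(self.mu)

    def __getitem__(self, i: int) -> GaussianPrimitive:
        return GaussianPrimitive(self.mu[i], self.rot[i], self.scale[i],
                                 self.opacity[i], self.color[i])

    @classmethod
    def from_primitives(cls, prims) -> "SplatSet":
        prims = list(prims)
        if not prims:
            raise ValueError("empty splat set")
        return cls(mu=np.stack([p.mu for p in prims]),
                   rot=np.stack([p.rot for p in prims]),
                   scale=np.stack([p.scale for p in prims]),
                   opacity=np.array([p.opacity for p in prims]),
                   color=np.stack([p.color for p in prims]))


_REQUIRED = ("x", "y", "z", "scale_0", "scale_1", "scale_2",
             "rot_0", "rot_1", "rot_2", "rot_3", "opacity",
             "f_dc_0", "f_dc_1", "f_dc_2")


def load_splats(path) -> SplatSet:
    """Load a splat PLY: exp the log-scales, squash the opacity logit, map the
    DC spherical-harmonic coefficients to RGB via ``0.5 + C0 * f_dc`` and
    normalize the quaternions."""
    fields = read_ply(path)
    for name in _REQUIRED:
        if name not in fields:
            raise PlyError(f"{path}: missing splat field {name!r}")
    cols = {name: np.asarray(fields[name], dtype=np.float64) for name in _REQUIRED}
    for name, a in cols.items():
        if not np.all(np.isfinite(a)):
            raise PlyError(f"{path}: non-finite values in {name!r}")
    mu = np.column_stack([cols["x"], cols["y"], cols["z"]])
    scale = np.exp(np.column_stack([cols["scale_0"], cols["scale_1"], cols["scale_2"]]))
    rot = np.column_stack([cols["rot_0"], cols["rot_1"], cols["rot_2"], cols["rot_3"]])
    opacity = 1.0 / (1.0 + np.exp(-cols["opacity"]))
    color = np.clip(0.5 + SH_C0 * np.column_stack(
        [cols["f_dc_0"], cols["f_dc_1"], cols["f_dc_2"]]), 0.0, 1.0)
    if len(mu) == 0:
        raise PlyError(f"{path}: empty splat set")
    return SplatSet(mu=mu, rot=rot, scale=scale, opacity=opacity, color=color)


def allocate_draws(splats: SplatSet, budget: int) -> np.ndarray:
    """Per-primitive draw counts: proportional to opacity * geometric-mean sigma,
    zero below the opacity floor, scaled so the total is ~``budget``."""
    weight = splats.opacity * np.cbrt(splats.scale.prod(axis=1))
    weight = np.where(splats.opacity < MIN_OPACITY, 0.0, weight)
    total = weight.sum()
    if total <= 0:
        return np.zeros(len(splats), dtype=np.int64)
    return np.round(weight / total * budget).astype(np.int64)


def sample_points(splats: SplatSet, budget: int = 100_000,
                  mahal_max: float = 3.0, seed: int = 0) -> PointCloud:
    """Draw ~``budget`` points from the scene's Gaussians and reject draws with
    Mahalanobis distance above ``mahal_max``.

    A draw for primitive i is mu_i + R_i S_i z with z ~ N(0, I); its
    Mahalanobis distance to the primitive is exactly ||z||, so rejection is
    performed in the whitened frame.  Point color is the primitive color.
    Identical seeds give identical clouds.
    """
    if mahal_max <= 0:
        raise ValueError("mahal_max must be positive")
    if len(splats) == 0:
        raise ValueError("empty splat set")
    if np.any(splats.scale < 1e-12):
        raise ValueError("degenerate (near-singular) primitive scale")
    draws = allocate_draws(splats, budget)
    rng = np.random.default_rng(seed)
    rots = quat_to_matrix(splats.rot)
    pts, cols = [], []
    for i in np.nonzero(draws)[0]:
        z = rng.standard_normal((draws[i], 3))
        keep = np.einsum("ij,ij->i", z, z) <= mahal_max ** 2
        z = z[keep]
        local = z * splats.scale[i]
        pts.append(splats.mu[i] + local @ rots[i].T)
        cols.append(np.broadcast_to(splats.color[i], (len(z), 3)))
    if not pts:
        return PointCloud(points=np.empty((0, 3)), colors=np.empty((0, 3)))
    return PointCloud(points=np.vstack(pts), colors=np.vstack(cols))
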