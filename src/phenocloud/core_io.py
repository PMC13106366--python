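"""Domain types and point-cloud I/O shared by every pipeline stage.

The universal currency is :class:`PointCloud`: XYZ coordinates in meters
(z-up after ground alignment), per-point RGB in [0, 1], and optional unit
normals, curvature scalars and integer instance labels (0 = unassigned or
ground, k >= 1 = plant k).

Supported formats: PLY (ASCII and binary little-endian) and PCD v0.7 ASCII,
plus a CSV label sidecar (``point_index,label``, 0-based indices) that carries
instance annotations which neither format standardizes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from ._ply import PlyError, read_ply, write_ply

__all__ = [
    "PointCloud", "read_point_cloud", "write_point_cloud",
    "read_label_sidecar", "write_label_sidecar", "sidecar_path",
]

_MID_GRAY = 0.5


@dataclasses.dataclass
class PointCloud:
    """A colored 3-D point set with optional per-point channels.

    Invariants (checked on construction): all channels share the point count,
    colors lie in [0, 1]^3, normals are unit length within 1e-6 where present.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    normals: np.ndarray | None = None
    curvatures: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        n = len(self.points)
        if self.colors is None:
            self.colors = np.full((n, 3), _MID_GRAY)
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.colors.shape != (n, 3):
            raise ValueError("colors must match points in length")
        if self.colors.size and (self.colors.min() < -1e-9 or self.colors.max() > 1 + 1e-9):
            raise ValueError("colors must lie in [0, 1]")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise ValueError("normals must match points in length")
            norms = np.linalg.norm(self.normals, axis=1)
            if norms.size and np.abs(norms - 1.0).max() > 1e-6:
                raise ValueError("normals must be unit length within 1e-6")
        if self.curvatures is not None:
            self.curvatures = np.asarray(self.curvatures, dtype=np.float64)
            if self.curvatures.shape != (n,):
                raise ValueError("curvatures must be (n,)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise ValueError("labels must be (n,)")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given indices/mask; every channel is sliced."""
        return PointCloud(
            points=self.points[index],
            colors=self.colors[index],
            normals=None if self.normals is None else self.normals[index],
            curvatures=None if self.curvatures is None else self.curvatures[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def with_(self, **channels) -> "PointCloud":
        """Copy with some channels replaced (e.g. ``with_(labels=...)``)."""
        kw = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        kw.update(channels)
        return PointCloud(**kw)


def sidecar_path(path) -> Path:
    """Conventional label-sidecar location for a cloud file."""
    p = Path(path)
    return p.with_suffix(p.suffix + ".labels.csv")


def read_label_sidecar(path, n_points: int) -> np.ndarray:
    """Read a ``point_index,label`` CSV into a dense length-n label array."""
    df = pd.read_csv(path)
    if not {"point_index", "label"} <= set(df.columns):
        raise ValueError(f"{path}: sidecar needs columns point_index,label")
    idx = df["point_index"].to_numpy(dtype=np.int64)
    if len(np.unique(idx)) != len(idx):
        raise ValueError(f"{path}: duplicate point_index in sidecar")
    if idx.size and (idx.min() < 0 or idx.max() >= n_points):
        raise ValueError(f"{path}: sidecar index out of range for {n_points} points")
    labels = np.zeros(n_points, dtype=np.int64)
    labels[idx] = df["label"].to_numpy(dtype=np.int64)
    return labels


def write_label_sidecar(path, labels: np.ndarray) -> Path:
    labels = np.asarray(labels, dtype=np.int64)
    pd.DataFrame({"point_index": np.arange(len(labels)), "label": labels}
                 ).to_csv(path, index=False)
    return Path(path)


def _read_pcd(path) -> PointCloud:
    """PCD v0.7 ASCII with fields x y z and optionally packed ``rgb``."""
    meta: dict[str, list[str]] = {}
    rows = []
    with open(path, "r") as fh:
        in_header = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_header:
                key, *vals = line.split()
                meta[key.upper()] = vals
                if key.upper() == "DATA":
                    if vals[0] != "ascii":
                        raise ValueError(f"{path}: only ascii PCD supported")
                    in_header = False
                continue
            rows.append(line.split())
    if "FIELDS" not in meta:
        raise ValueError(f"{path}: malformed PCD header (no FIELDS)")
    fields = meta["FIELDS"]
    data = np.asarray(rows, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != len(fields):
        raise ValueError(f"{path}: PCD row width does not match FIELDS")
    cols = {name: data[:, j] for j, name in enumerate(fields)}
    if not {"x", "y", "z"} <= cols.keys():
        raise ValueError(f"{path}: PCD must contain x y z")
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    colors = None
    if "rgb" in cols:
        packed = cols["rgb"].astype(np.float32).view(np.uint32)
        colors = np.column_stack([(packed >> 16) & 0xFF,
                                  (packed >> 8) & 0xFF,
                                  packed & 0xFF]).astype(np.float64) / 255.0
    return PointCloud(points=points, colors=colors)


def _write_pcd(cloud: PointCloud, path) -> None:
    n = len(cloud)
    rgb = np.clip(np.round(cloud.colors * 255), 0, 255).astype(np.uint32)
    packed = ((rgb[:, 0] << 16) | (rgb[:, 1] << 8) | rgb[:, 2]).view(np.int32)
    rgbf = packed.astype(np.int32).view(np.float32).astype(np.float64)
    header = "\n".join([
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS x y z rgb",
        "SIZE 4 4 4 4",
        "TYPE F F F F",
        "COUNT 1 1 1 1",
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        "DATA ascii",
    ])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for (x, y, z), c in zip(cloud.points, rgbf):
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {float(c)!r}\n")


def read_point_cloud(path, label_path=None) -> PointCloud:
    """Read a PLY or PCD point cloud, optionally attaching a label sidecar.

    Colors default to mid-gray when the file has none; 0-255 integer color is
    rescaled to [0, 1].
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    ext = p.suffix.lower()
    if ext == ".ply":
        fields = read_ply(p)
        for req in ("x", "y", "z"):
            if req not in fields:
                raise PlyError(f"{p}: missing vertex property {req!r}")
        points = np.column_stack([fields["x"], fields["y"], fields["z"]]).astype(np.float64)
        colors = None
        if {"red", "green", "blue"} <= fields.keys():
            rgb = np.column_stack([fields["red"], fields["green"], fields["blue"]])
            colors = rgb.astype(np.float64)
            if rgb.dtype.kind in "ui" or colors.max(initial=0.0) > 1.0 + 1e-9:
                colors = colors / 255.0
            colors = np.clip(colors, 0.0, 1.0)
        normals = None
        if {"nx", "ny", "nz"} <= fields.keys():
            normals = np.column_stack([fields["nx"], fields["ny"], fields["nz"]]).astype(np.float64)
            norm = np.linalg.norm(normals, axis=1)
            normals = normals / np.where(norm > 0, norm, 1.0)[:, None]
        curv = fields.get("curvature")
        cloud = PointCloud(points=points, colors=colors, normals=normals,
                           curvatures=None if curv is None else curv.astype(np.float64))
    elif ext == ".pcd":
        cloud = _read_pcd(p)
    else:
        raise ValueError(f"unsupported point-cloud extension: {ext!r}")

    if label_path is None and sidecar_path(p).exists():
        label_path = sidecar_path(p)
    if label_path is not None:
        cloud = cloud.with_(labels=read_label_sidecar(label_path, len(cloud)))
    return cloud


def write_point_cloud(cloud: PointCloud, path, with_labels: bool = False,
                      binary: bool = True) -> list[Path]:
    """Write a cloud as PLY (default binary) or PCD; optionally a label sidecar.

    Returns the list of files written. An empty cloud is an error: silently
    writing a pointless file would hide upstream failures.
    """
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    p = Path(path)
    ext = p.suffix.lower()
    written = [p]
    if ext == ".ply":
        fields = {
            "x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2],
            "red": np.clip(np.round(cloud.colors[:, 0] * 255), 0, 255).astype(np.uint8),
            "green": np.clip(np.round(cloud.colors[:, 1] * 255), 0, 255).astype(np.uint8),
            "blue": np.clip(np.round(cloud.colors[:, 2] * 255), 0, 255).astype(np.uint8),
        }
        if cloud.normals is not None:
            fields["nx"], fields["ny"], fields["nz"] = cloud.normals.T
        if cloud.curvatures is not None:
            fields["curvature"] = cloud.curvatures
        write_ply(p, fields, binary=binary)
    elif ext == ".pcd":
        _write_pcd(cloud, p)
    else:
        raise ValueError(f"unsupported point-cloud extension: {ext!r}")
    if with_labels and cloud.labels is not None:
        written.append(write_label_sidecar(sidecar_path(p), cloud.labels))
    return written
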