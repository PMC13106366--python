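"""Minimal PLY vertex-element codec.

Reads/writes point-data PLY files (``element vertex`` only) in both ASCII and
binary little-endian dialects, preserving arbitrary per-vertex scalar
properties.  This covers colored/normal-bearing point clouds as well as the
Gaussian-splat PLY dialect (``scale_0..2``, ``rot_0..3``, ``opacity``,
``f_dc_0..2``).  Mesh faces and list properties are out of scope.
"""

from __future__ import annotations

import numpy as np

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}
_INV_DTYPES = {
    "u1": "uchar", "i1": "char", "u2": "ushort", "i2": "short",
    "i4": "int", "u4": "uint", "f4": "float", "f8": "double",
}


class PlyError(ValueError):
    """Malformed or unsupported PLY content."""


def read_ply(path) -> dict[str, np.ndarray]:
    """Read the vertex element of a PLY file into a dict of 1-D arrays."""
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise PlyError(f"{path}: not a PLY file (missing header)")
    end = data.index(b"\n", end) + 1
    header = data[:end].decode("ascii", errors="replace").splitlines()
    body = data[end:]

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyError(f"{path}: list properties unsupported")
            if tok[1] not in _PLY_DTYPES:
                raise PlyError(f"{path}: unknown property type {tok[1]!r}")
            props.append((tok[2], _PLY_DTYPES[tok[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyError(f"{path}: unsupported format {fmt!r}")
    if n_vertex is None:
        raise PlyError(f"{path}: no vertex element")
    if not props:
        raise PlyError(f"{path}: vertex element has no properties")

    if fmt == "ascii":
        rows = np.loadtxt(
            [ln for ln in body.decode("ascii").splitlines() if ln.strip()],
            dtype=np.float64, ndmin=2, max_rows=n_vertex,
        )
        if rows.shape != (n_vertex, len(props)):
            raise PlyError(f"{path}: expected {n_vertex}x{len(props)} values")
        out = {}
        for j, (name, dt) in enumerate(props):
            out[name] = rows[:, j].astype(np.dtype("<" + dt))
    else:
        dtype = np.dtype([(name, "<" + dt) for name, dt in props])
        need = dtype.itemsize * n_vertex
        if len(body) < need:
            raise PlyError(f"{path}: truncated binary body")
        rec = np.frombuffer(body[:need], dtype=dtype)
        out = {name: np.ascontiguousarray(rec[name]) for name, _ in props}
    return out


def write_ply(path, fields: dict[str, np.ndarray], binary: bool = True) -> None:
    """Write 1-D arrays as a single PLY vertex element.

    Array dtypes are preserved (uint8 color stays ``uchar``, float64 stays
    ``double``); all arrays must share one length.
    """
    names = list(fields)
    n = len(fields[names[0]])
    cols = []
    for name in names:
        a = np.asarray(fields[name])
        if a.ndim != 1 or len(a) != n:
            raise PlyError(f"field {name!r}: expected 1-D length {n}")
        key = a.dtype.str.lstrip("<>=|")
        if key not in _INV_DTYPES:
            a = a.astype(np.float64)
            key = "f8"
        cols.append((name, a.astype("<" + key), _INV_DTYPES[key]))

    lines = ["ply",
             f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
             f"element vertex {n}"]
    lines += [f"property {ply_t} {name}" for name, _, ply_t in cols]
    lines.append("end_header")
    header = ("\n".join(lines) + "\n").encode("ascii")

    with open(path, "wb") as fh:
        fh.write(header)
        if binary:
            rec = np.empty(n, dtype=[(name, a.dtype) for name, a, _ in cols])
            for name, a, _ in cols:
                rec[name] = a
            fh.write(rec.tobytes())
        else:
            mat = np.column_stack([a.astype(np.float64) for _, a, _ in cols])
            int_mask = [a.dtype.kind in "ui" for _, a, _ in cols]
            for row in mat:
                fh.write((" ".join(
                    str(int(v)) if is_int else repr(float(v))
                    for v, is_int in zip(row, int_mask)) + "\n").encode("ascii"))
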