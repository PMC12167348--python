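"""Minimal PLY / STL readers and writers for meshes and point clouds.

Supports ascii and binary-little-endian PLY with x/y/z (and optional
nx/ny/nz) vertex properties and triangular faces, plus ascii and binary STL.
Only what the pipeline needs — not a general-purpose PLY implementation.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .registration import PointCloud, SurfaceMesh

__all__ = ["save_ply", "load_ply", "save_stl", "load_stl", "load_surface"]

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


def save_ply(obj, path, binary: bool = False) -> None:
    """Write a SurfaceMesh or PointCloud as PLY (ascii by default)."""
    path = Path(path)
    if isinstance(obj, SurfaceMesh):
        verts, normals, faces = obj.vertices, None, obj.faces
    elif isinstance(obj, PointCloud):
        verts, normals, faces = obj.points, obj.normals, None
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as PLY")

    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0"]
    header.append(f"element vertex {len(verts)}")
    header += ["property double x", "property double y", "property double z"]
    if normals is not None:
        header += ["property double nx", "property double ny", "property double nz"]
    if faces is not None:
        header.append(f"element face {len(faces)}")
        header.append("property list uchar int vertex_indices")
    header.append("end_header")

    vdata = verts if normals is None else np.hstack([verts, normals])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(vdata.astype("<f8").tobytes())
            if faces is not None:
                for f in faces:
                    fh.write(struct.pack("<Biii", 3, *map(int, f)))
        else:
            for row in vdata:
                fh.write((" ".join(f"{x:.17g}" for x in row) + "\n").encode())
            if faces is not None:
                for f in faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode())


def load_ply(path):
    """Read a PLY file; returns SurfaceMesh if faces are present, else PointCloud."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise ValueError("not a PLY file (no end_header)")
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:]
    body = body[body.find(b"\n") + 1:]

    fmt = None
    elements = []  # (name, count, [(prop_name, type, is_list, list_count_type)])
    for line in header_lines:
        tok = line.strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if tok[1] == "list":
                elements[-1][2].append((tok[4], tok[3], True, tok[2]))
            else:
                elements[-1][2].append((tok[2], tok[1], False, None))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")

    data = {}
    if fmt == "ascii":
        tokens = body.decode("ascii").split()
        pos = 0
        for name, count, props in elements:
            rows = []
            for _ in range(count):
                row = {}
                for pname, ptype, is_list, _ in props:
                    if is_list:
                        n = int(tokens[pos]); pos += 1
                        row[pname] = [int(float(tokens[pos + i])) for i in range(n)]
                        pos += n
                    else:
                        row[pname] = float(tokens[pos]); pos += 1
                rows.append(row)
            data[name] = rows
    else:
        pos = 0
        for name, count, props in elements:
            rows = []
            for _ in range(count):
                row = {}
                for pname, ptype, is_list, ctype in props:
                    if is_list:
                        cdt, csz = _PLY_TYPES[ctype]
                        n = int(np.frombuffer(body, cdt, 1, pos)[0]); pos += csz
                        dt, sz = _PLY_TYPES[ptype]
                        row[pname] = np.frombuffer(body, dt, n, pos).astype(int).tolist()
                        pos += sz * n
                    else:
                        dt, sz = _PLY_TYPES[ptype]
                        row[pname] = float(np.frombuffer(body, dt, 1, pos)[0])
                        pos += sz
                rows.append(row)
            data[name] = rows

    vrows = data.get("vertex", [])
    verts = np.array([[r["x"], r["y"], r["z"]] for r in vrows]).reshape(-1, 3)
    normals = None
    if vrows and "nx" in vrows[0]:
        normals = np.array([[r["nx"], r["ny"], r["nz"]] for r in vrows])
    frows = data.get("face", [])
    if frows:
        key = "vertex_indices" if "vertex_indices" in frows[0] else "vertex_index"
        faces = np.array([r[key] for r in frows], dtype=np.int64)
        return SurfaceMesh(verts, faces)
    return PointCloud(verts, normals)


def save_stl(mesh: SurfaceMesh, path, name: str = "mesh") -> None:
    """Write an ascii STL (vertices are duplicated per facet by the format)."""
    normals = mesh.face_normals()
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for f, n in zip(mesh.faces, normals):
            fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            fh.write("    outer loop\n")
            for vi in f:
                v = mesh.vertices[vi]
                fh.write(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {name}\n")


def load_stl(path) -> SurfaceMesh:
    """Read ascii or binary STL; duplicated vertices are merged exactly."""
    raw = Path(path).read_bytes()
    is_ascii = raw.lstrip().startswith(b"solid") and b"facet" in raw[:2048]
    tris = []
    if is_ascii:
        text = raw.decode("ascii", errors="replace").split()
        i = 0
        while i < len(text):
            if text[i] == "vertex":
                tris.append([float(text[i + 1]), float(text[i + 2]), float(text[i + 3])])
                i += 4
            else:
                i += 1
    else:
        n = struct.unpack_from("<I", raw, 80)[0]
        rec = np.frombuffer(raw, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
        floats = rec[:, :48].copy().view("<f4").reshape(n, 12)
        tris = floats[:, 3:12].reshape(-1, 3).astype(float)
    tris = np.asarray(tris, dtype=float).reshape(-1, 3)
    if len(tris) % 3:
        raise ValueError("STL facet/vertex count mismatch")
    verts, inverse = np.unique(tris, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(verts, faces)


def load_surface(path) -> SurfaceMesh:
    """Load a mesh from PLY or STL based on the file suffix."""
    suffix = Path(path).suffix.lower()
    if suffix == ".ply":
        obj = load_ply(path)
        if not isinstance(obj, SurfaceMesh):
            raise ValueError("PLY file contains no faces")
        return obj
    if suffix == ".stl":
        return load_stl(path)
    raise ValueError(f"unsupported mesh format {suffix!r}")
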