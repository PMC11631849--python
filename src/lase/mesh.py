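"""Triangular surface meshes of the left atrium.

The atrial chamber is represented as a triangulated surface: an ``(n, 3)``
array of vertex coordinates in millimetres and an ``(m, 3)`` array of
0-based vertex indices.  All downstream processing (point association,
voltage mapping, entropy) treats the vertex set of this mesh as its spatial
domain, so the invariants enforced here — triangles only, valid indices, no
degenerate faces, no unreferenced vertices — are load-bearing.

Supported interchange formats are OFF, PLY (ascii and binary little-endian)
and legacy-VTK polydata.  The readers are deliberately strict: a
non-triangular face is an error, never silently triangulated, because face
splitting would reorder the surface without the caller's knowledge.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtrialMesh",
    "MeshError",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "vertex_normals",
]


class MeshError(ValueError):
    """A mesh violates a structural invariant."""


class MeshFormatError(MeshError):
    """A mesh file cannot be parsed; the message names the offending construct."""


@dataclass
class AtrialMesh:
    """A triangulated atrial surface: vertices in mm, faces as index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array of vertex triples")

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        """Area-weighted centroid of the surface (mm)."""
        v = self.vertices
        f = self.faces
        tri_c = v[f].mean(axis=1)
        w = self.face_areas()
        if w.sum() == 0:
            return v.mean(axis=0)
        return (tri_c * w[:, None]).sum(axis=0) / w.sum()

    def edges(self, unique: bool = True) -> np.ndarray:
        """All edges as (k, 2) sorted index pairs; deduplicated by default."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        if unique:
            e = np.unique(e, axis=0)
        return e

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = self.edges(unique=False)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def vertex_adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b in self.edges():
            adj[a].add(int(b))
            adj[b].add(int(a))
        return adj

    def vertex_faces(self) -> list[list[int]]:
        vf: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, (a, b, c) in enumerate(self.faces):
            vf[a].append(i)
            vf[b].append(i)
            vf[c].append(i)
        return vf

    # -- invariants --------------------------------------------------------

    def validate(self) -> "AtrialMesh":
        """Raise :class:`MeshError` unless all structural invariants hold."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshError("empty mesh")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshError("face index out of range")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise MeshError("degenerate face with repeated vertex")
        referenced = np.zeros(self.n_vertices, dtype=bool)
        referenced[self.faces] = True
        if not referenced.all():
            idx = np.flatnonzero(~referenced)[:10].tolist()
            raise MeshError(f"unreferenced vertices present (e.g. {idx})")
        return self

    def clean(self) -> "AtrialMesh":
        """Return a copy with degenerate faces and unreferenced vertices removed."""
        f = self.faces
        keep = ~(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        f = f[keep]
        referenced = np.zeros(self.n_vertices, dtype=bool)
        if len(f):
            referenced[f] = True
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[referenced] = np.arange(int(referenced.sum()))
        return AtrialMesh(self.vertices[referenced], remap[f])

    def copy(self) -> "AtrialMesh":
        return AtrialMesh(self.vertices.copy(), self.faces.copy())

    def __eq__(self, other: object) -> bool:  # vertex-order-sensitive equality
        if not isinstance(other, AtrialMesh):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and self.faces.shape == other.faces.shape
            and np.allclose(self.vertices, other.vertices, atol=1e-9)
            and np.array_equal(self.faces, other.faces)
        )


# ---------------------------------------------------------------------------
# vertex normals


def vertex_normals(mesh: AtrialMesh, weighting: str = "area") -> np.ndarray:
    """Outward unit normal at every vertex.

    Each vertex normal is the normalized weighted mean of its incident face
    normals; ``weighting`` is ``"area"`` (default, weights proportional to
    triangle area) or ``"uniform"``.  Orientation is fixed globally: if the
    mean dot product between the normals and the radial direction from the
    surface centroid is negative the whole field is flipped, so that closed,
    star-shaped chambers always carry outward normals.

    Raises :class:`MeshError` when a vertex has no incident face or only
    zero-area incident faces.
    """
    mesh.validate()
    if weighting not in ("area", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    if weighting == "uniform":
        norms = np.linalg.norm(fn, axis=1)
        bad = norms == 0
        if bad.any():
            raise MeshError(
                f"zero-area faces at indices {np.flatnonzero(bad)[:10].tolist()}"
            )
        fn = fn / norms[:, None]
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], fn)
    lens = np.linalg.norm(acc, axis=1)
    bad = lens == 0
    if bad.any():
        raise MeshError(
            "vertices with undefined normal (isolated or zero-area-only): "
            f"{np.flatnonzero(bad)[:10].tolist()}"
        )
    normals = acc / lens[:, None]
    radial = v - mesh.centroid()
    if float(np.einsum("ij,ij->i", normals, radial).mean()) < 0:
        normals = -normals
    return normals


# ---------------------------------------------------------------------------
# readers


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = path.suffix.lower().lstrip(".")
    if ext in ("ply", "off", "vtk"):
        return ext
    raise MeshFormatError(f"cannot infer mesh format from extension {path.suffix!r}")


def read_mesh(path: str | Path, format: str | None = None) -> AtrialMesh:
    """Read an OFF / PLY / legacy-VTK polydata file into an :class:`AtrialMesh`.

    Coordinates pass through unchanged (millimetres assumed).  The mesh is
    cleaned (degenerate faces and unreferenced vertices dropped) and
    validated before being returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "off":
        mesh = _read_off(path)
    elif fmt == "ply":
        mesh = _read_ply(path)
    elif fmt == "vtk":
        mesh = _read_vtk(path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    return mesh.clean().validate()


def _data_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def _read_off(path: Path) -> AtrialMesh:
    lines = _data_lines(path.read_text())
    if not lines or not lines[0].startswith("OFF"):
        raise MeshFormatError("OFF: missing 'OFF' header")
    rest = lines[0][3:].split()
    lines = lines[1:]
    if not rest:
        if not lines:
            raise MeshFormatError("OFF: missing counts line")
        rest = lines[0].split()
        lines = lines[1:]
    try:
        nv, nf = int(rest[0]), int(rest[1])
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"OFF: bad counts line {rest!r}") from exc
    if len(lines) < nv + nf:
        raise MeshFormatError("OFF: truncated file")
    try:
        verts = np.array(
            [[float(t) for t in lines[i].split()[:3]] for i in range(nv)]
        )
    except ValueError as exc:
        raise MeshFormatError(f"OFF: bad vertex line: {exc}") from exc
    faces = []
    for i in range(nv, nv + nf):
        toks = lines[i].split()
        k = int(toks[0])
        if k != 3:
            raise MeshFormatError(f"OFF: non-triangular face with {k} vertices")
        faces.append([int(toks[1]), int(toks[2]), int(toks[3])])
    return AtrialMesh(verts.reshape(nv, 3), np.array(faces, dtype=np.int64))


_PLY_TYPES = {
    "char": ("b", 1), "int8": ("b", 1),
    "uchar": ("B", 1), "uint8": ("B", 1),
    "short": ("h", 2), "int16": ("h", 2),
    "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4),
    "uint": ("I", 4), "uint32": ("I", 4),
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
}


def _read_ply(path: Path) -> AtrialMesh:
    raw = path.read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise MeshFormatError("PLY: missing ply/end_header")
    nl = raw.find(b"\n", end)
    header = raw[:nl].decode("ascii", errors="replace")
    body = raw[nl + 1 :]

    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, properties)
    for line in header.splitlines():
        toks = line.strip().split()
        if not toks or toks[0] in ("ply", "comment", "obj_info"):
            continue
        if toks[0] == "format":
            fmt = toks[1]
        elif toks[0] == "element":
            elements.append((toks[1], int(toks[2]), []))
        elif toks[0] == "property":
            if not elements:
                raise MeshFormatError("PLY: property before element")
            if toks[1] == "list":
                elements[-1][2].append(("list", toks[2], toks[3], toks[4]))
            else:
                elements[-1][2].append(("scalar", toks[1], toks[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"PLY: unsupported format {fmt!r}")

    verts = None
    faces = None
    if fmt == "ascii":
        tokens = body.decode("ascii").split()
        pos = 0
        for name, count, props in elements:
            rows = []
            for _ in range(count):
                row = {}
                for p in props:
                    if p[0] == "list":
                        k = int(float(tokens[pos])); pos += 1
                        row[p[3]] = [int(float(tokens[pos + j])) for j in range(k)]
                        pos += k
                    else:
                        row[p[2]] = float(tokens[pos]); pos += 1
                rows.append(row)
            verts, faces = _ply_collect(name, rows, verts, faces)
    else:
        pos = 0
        for name, count, props in elements:
            rows = []
            for _ in range(count):
                row = {}
                for p in props:
                    if p[0] == "list":
                        cfmt, csz = _PLY_TYPES[p[1]]
                        k = struct.unpack_from("<" + cfmt, body, pos)[0]
                        pos += csz
                        ifmt, isz = _PLY_TYPES[p[2]]
                        vals = struct.unpack_from("<" + ifmt * k, body, pos)
                        pos += isz * k
                        row[p[3]] = [int(x) for x in vals]
                    else:
                        sfmt, ssz = _PLY_TYPES[p[1]]
                        row[p[2]] = struct.unpack_from("<" + sfmt, body, pos)[0]
                        pos += ssz
                rows.append(row)
            verts, faces = _ply_collect(name, rows, verts, faces)
    if verts is None:
        raise MeshFormatError("PLY: no vertex element")
    if faces is None:
        raise MeshFormatError("PLY: no face element")
    return AtrialMesh(verts, faces)


def _ply_collect(name, rows, verts, faces):
    if name == "vertex":
        try:
            verts = np.array([[r["x"], r["y"], r["z"]] for r in rows])
        except KeyError as exc:
            raise MeshFormatError(f"PLY: vertex missing coordinate {exc}") from exc
    elif name == "face":
        out = []
        for r in rows:
            idx = r.get("vertex_indices", r.get("vertex_index"))
            if idx is None:
                raise MeshFormatError("PLY: face element without vertex_indices")
            if len(idx) != 3:
                raise MeshFormatError(
                    f"PLY: non-triangular face with {len(idx)} vertices"
                )
            out.append(idx)
        faces = np.array(out, dtype=np.int64).reshape(len(out), 3)
    return verts, faces


def _read_vtk(path: Path) -> AtrialMesh:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise MeshFormatError("VTK: missing '# vtk DataFile' header")
    upper = [ln.upper() for ln in lines]
    if "ASCII" not in upper:
        raise MeshFormatError("VTK: only ASCII legacy files supported")
    if not any(ln.startswith("DATASET POLYDATA") for ln in upper):
        raise MeshFormatError("VTK: DATASET POLYDATA required")

    def _section(keyword: str) -> tuple[int, list[str]]:
        for i, ln in enumerate(upper):
            if ln.startswith(keyword):
                return i, lines[i].split()
        raise MeshFormatError(f"VTK: missing {keyword} section")

    i, toks = _section("POINTS")
    n_pts = int(toks[1])
    vals: list[float] = []
    j = i + 1
    while len(vals) < 3 * n_pts and j < len(lines):
        if upper[j].startswith(("POLYGONS", "TRIANGLE_STRIPS", "LINES", "VERTICES")):
            break
        vals.extend(float(t) for t in lines[j].split())
        j += 1
    if len(vals) < 3 * n_pts:
        raise MeshFormatError("VTK: truncated POINTS section")
    verts = np.array(vals[: 3 * n_pts]).reshape(n_pts, 3)

    i, toks = _section("POLYGONS")
    n_poly = int(toks[1])
    total = int(toks[2])
    ints: list[int] = []
    j = i + 1
    while len(ints) < total and j < len(lines):
        try:
            ints.extend(int(t) for t in lines[j].split())
        except ValueError as exc:
            raise MeshFormatError(f"VTK: bad POLYGONS line {lines[j]!r}") from exc
        j += 1
    faces = []
    pos = 0
    for _ in range(n_poly):
        if pos >= len(ints):
            raise MeshFormatError("VTK: truncated POLYGONS section")
        k = ints[pos]
        if k != 3:
            raise MeshFormatError(f"VTK: non-triangular polygon with {k} vertices")
        faces.append(ints[pos + 1 : pos + 4])
        pos += 4
    return AtrialMesh(verts, np.array(faces, dtype=np.int64).reshape(len(faces), 3))


# ---------------------------------------------------------------------------
# writers


def write_mesh(
    mesh: AtrialMesh,
    path: str | Path,
    format: str | None = None,
    binary: bool = False,
) -> None:
    """Write a mesh so that :func:`read_mesh` returns an equal mesh.

    Vertex order is preserved exactly.  ``binary`` selects binary
    little-endian output for PLY (ignored elsewhere).
    """
    mesh.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "off":
        _write_off(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, binary=binary)
    elif fmt == "vtk":
        _write_vtk(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def _write_off(mesh: AtrialMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def _write_ply(mesh: AtrialMesh, path: Path, binary: bool = False) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(np.ascontiguousarray(mesh.vertices, "<f8").tobytes())
            for a, b, c in mesh.faces:
                fh.write(struct.pack("<Biii", 3, a, b, c))
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for x, y, z in mesh.vertices:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            for a, b, c in mesh.faces:
                fh.write(f"3 {a} {b} {c}\n")


def _write_vtk(mesh: AtrialMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natrial mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")
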