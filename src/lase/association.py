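"""Association of EGM acquisition points with mesh vertices.

During mapping, each bipolar electrogram is stored with the 3D catheter
position at acquisition time.  Because the atrial wall moves and deforms,
a recording is allowed to sit a little off the reconstructed surface: a
point is attributed to a vertex when it lies inside a sphere of radius
8 mm centred on the vertex *and* within 2 mm of the line through the
vertex along its outward normal (a spherically capped cylinder).  Points
behind the surface are kept deliberately — wall deformation moves
recordings to either side of the reconstructed shell.

The spatial index (a KD-tree over the point cloud) is an acceleration
detail only; the result is contractually identical to the brute-force
double loop over all vertex-point pairs, and both code paths are exposed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .mesh import AtrialMesh

__all__ = [
    "EgmPoint",
    "AssociationSpec",
    "NeighborSet",
    "associate",
    "coverage_report",
    "read_points",
    "write_points",
    "TRACE_DURATION_S",
    "AU_PER_MV",
]

TRACE_DURATION_S = 2.5
#: conversion between mapping-system arbitrary units and millivolts
MV_PER_AU = 0.003
AU_PER_MV = 1.0 / MV_PER_AU


@dataclass
class EgmPoint:
    """One acquisition site: position (mm) plus a 2.5-s bipolar trace (a.u.)."""

    point_id: str
    position: np.ndarray
    trace: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.trace = np.asarray(self.trace, dtype=np.float64).ravel()

    def validate(self) -> "EgmPoint":
        if self.sample_rate <= 0:
            raise ValueError(f"point {self.point_id}: sample_rate must be > 0")
        expected = round(TRACE_DURATION_S * self.sample_rate)
        if len(self.trace) != expected:
            raise ValueError(
                f"point {self.point_id}: trace has {len(self.trace)} samples, "
                f"expected {expected} for {TRACE_DURATION_S} s at "
                f"{self.sample_rate} Hz"
            )
        if not np.all(np.isfinite(self.trace)) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"point {self.point_id}: non-finite values")
        return self


@dataclass
class AssociationSpec:
    """Sphere and cylinder radii (mm) of the neighborhood criterion."""

    sphere_radius: float = 8.0
    cylinder_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0 or self.cylinder_radius <= 0:
            raise ValueError("radii must be positive")
        if self.cylinder_radius > self.sphere_radius:
            raise ValueError("cylinder_radius must not exceed sphere_radius")


@dataclass
class NeighborSet:
    """Per-vertex ordered lists of EGM point indices (``N_v``)."""

    lists: list[np.ndarray]

    @property
    def n_vertices(self) -> int:
        return len(self.lists)

    @property
    def counts(self) -> np.ndarray:
        """Cardinality ``|N_v|`` for every vertex."""
        return np.array([len(l) for l in self.lists], dtype=np.int64)

    def __getitem__(self, v: int) -> np.ndarray:
        return self.lists[v]


def associate(
    mesh: AtrialMesh,
    normals: np.ndarray,
    points: list[EgmPoint],
    spec: AssociationSpec | None = None,
    method: str = "kdtree",
) -> NeighborSet:
    """Compute ``N_v`` for every vertex.

    ``point n in N_v`` iff ``|p_n - v| <= sphere_radius`` and the
    perpendicular distance from ``p_n`` to the infinite line through ``v``
    with direction ``normals[v]`` is ``<= cylinder_radius``.  Boundary
    distances are included.  Lists are ordered by ascending point index.
    """
    spec = spec or AssociationSpec()
    normals = np.asarray(normals, dtype=np.float64)
    if normals.shape != (mesh.n_vertices, 3):
        raise ValueError(
            f"normals shape {normals.shape} does not match mesh with "
            f"{mesh.n_vertices} vertices"
        )
    if len(points) == 0:
        return NeighborSet([np.empty(0, dtype=np.int64) for _ in range(mesh.n_vertices)])
    P = np.array([p.position for p in points])
    V = mesh.vertices
    r2 = spec.sphere_radius**2
    c2 = spec.cylinder_radius**2

    lists: list[np.ndarray] = []
    if method == "kdtree":
        tree = cKDTree(P)
        candidates = tree.query_ball_point(V, spec.sphere_radius)
        for v in range(mesh.n_vertices):
            idx = np.array(sorted(candidates[v]), dtype=np.int64)
            if len(idx) == 0:
                lists.append(idx)
                continue
            d = P[idx] - V[v]
            along = d @ normals[v]
            perp2 = np.einsum("ij,ij->i", d, d) - along**2
            keep = perp2 <= c2
            lists.append(idx[keep])
    elif method == "bruteforce":
        for v in range(mesh.n_vertices):
            d = P - V[v]
            d2 = np.einsum("ij,ij->i", d, d)
            along = d @ normals[v]
            perp2 = d2 - along**2
            keep = (d2 <= r2) & (perp2 <= c2)
            lists.append(np.flatnonzero(keep).astype(np.int64))
    else:
        raise ValueError(f"unknown association method {method!r}")
    return NeighborSet(lists)


def coverage_report(nset: NeighborSet) -> dict:
    """QC summary: how well the point cloud covers the mesh vertices."""
    counts = nset.counts
    n = len(counts)
    empty = int((counts == 0).sum())
    report = {
        "n_vertices": n,
        "n_empty": empty,
        "frac_empty": empty / n if n else 0.0,
        "mean_count": float(counts.mean()) if n else 0.0,
    }
    if n:
        q = np.percentile(counts, [0, 25, 50, 75, 100])
        report["count_quantiles"] = {
            "min": float(q[0]),
            "q25": float(q[1]),
            "median": float(q[2]),
            "q75": float(q[3]),
            "max": float(q[4]),
        }
    return report


# ---------------------------------------------------------------------------
# points interchange (CSV / JSON)


def read_points(path: str | Path) -> list[EgmPoint]:
    """Read EGM points from the CSV or JSON interchange format.

    CSV header: ``point_id,x_mm,y_mm,z_mm,sample_rate_hz`` followed either
    by inline sample columns ``s0..sN`` (a.u.) or by a ``trace_file``
    column naming a one-trace-per-line text file resolved relative to the
    CSV.  The JSON variant is a list of objects with the same fields plus
    an inline ``trace`` array.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_points_json(path)
    return _read_points_csv(path)


def _read_points_csv(path: Path) -> list[EgmPoint]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty points file")
        fields = reader.fieldnames
        required = ["point_id", "x_mm", "y_mm", "z_mm", "sample_rate_hz"]
        missing = [f for f in required if f not in fields]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        sample_cols = sorted(
            (f for f in fields if f.startswith("s") and f[1:].isdigit()),
            key=lambda f: int(f[1:]),
        )
        use_trace_file = "trace_file" in fields
        traces_cache: dict[str, list[np.ndarray]] = {}
        next_line: dict[str, int] = {}
        points = []
        for row in reader:
            pos = [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
            if use_trace_file:
                fname = row["trace_file"]
                if fname not in traces_cache:
                    tpath = path.parent / fname
                    traces_cache[fname] = [
                        np.array(ln.split(), dtype=float)
                        for ln in tpath.read_text().splitlines()
                        if ln.strip()
                    ]
                    next_line[fname] = 0
                # rows naming the same file consume its lines in order
                trace = traces_cache[fname][next_line[fname]]
                next_line[fname] += 1
            else:
                if not sample_cols:
                    raise ValueError(
                        f"{path}: neither s0..sN columns nor trace_file present"
                    )
                trace = np.array([float(row[c]) for c in sample_cols])
            points.append(
                EgmPoint(
                    point_id=row["point_id"],
                    position=np.array(pos),
                    trace=trace,
                    sample_rate=float(row["sample_rate_hz"]),
                ).validate()
            )
    return points


def _read_points_json(path: Path) -> list[EgmPoint]:
    data = json.loads(path.read_text())
    points = []
    for obj in data:
        points.append(
            EgmPoint(
                point_id=str(obj["point_id"]),
                position=np.array([obj["x_mm"], obj["y_mm"], obj["z_mm"]]),
                trace=np.array(obj["trace"], dtype=float),
                sample_rate=float(obj["sample_rate_hz"]),
            ).validate()
        )
    return points


def write_points(points: list[EgmPoint], path: str | Path) -> None:
    """Write points to CSV (inline ``s0..sN`` columns) or JSON by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = [
            {
                "point_id": p.point_id,
                "x_mm": p.position[0],
                "y_mm": p.position[1],
                "z_mm": p.position[2],
                "sample_rate_hz": p.sample_rate,
                "trace": p.trace.tolist(),
            }
            for p in points
        ]
        path.write_text(json.dumps(data))
        return
    if not points:
        path.write_text("point_id,x_mm,y_mm,z_mm,sample_rate_hz\n")
        return
    n_samples = len(points[0].trace)
    header = ["point_id", "x_mm", "y_mm", "z_mm", "sample_rate_hz"] + [
        f"s{i}" for i in range(n_samples)
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for p in points:
            writer.writerow(
                [p.point_id, *(f"{x:.9g}" for x in p.position), f"{p.sample_rate:.9g}"]
                + [f"{s:.9g}" for s in p.trace]
            )
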