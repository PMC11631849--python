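"""Voltage maps and left atrial spatial entropy (LASE).

The per-vertex voltage is the mean peak-to-peak amplitude (``max - min``
over the 2.5-s trace) of the EGM points associated with the vertex.  The
distribution of those per-vertex amplitudes over the whole chamber is
binned at a fixed width (100 a.u. = 0.3 mV, the scar-discrimination
cutoff reported for bipolar maps) and summarized by its Shannon entropy

    H = - sum_i p_i log2 p_i        (mode "plain", bits)

where ``p_i`` is the fraction of mapped vertices whose amplitude falls in
bin ``i``.  A homogeneous substrate spreads amplitude mass over many bins
(high H); fibrotic, patchy substrate concentrates it in the low bins
(low H).  Mode ``width_corrected`` adds the constant ``-log2(w_mV)``
(+1.737 bits at w = 0.3 mV), a density-style correction; both modes
differ by a constant at fixed bin width, so every comparative statistic
is mode-invariant.

Vertices with an empty neighborhood carry no amplitude and are excluded
from the histogram denominator by default (``denominator="valid"``); the
count of exclusions is reported.  ``denominator="all"`` implements the
literal all-vertex normalization instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .association import (
    AU_PER_MV,
    MV_PER_AU,
    AssociationSpec,
    EgmPoint,
    NeighborSet,
    associate,
    coverage_report,
    read_points,
)
from .config import RunConfig
from .mesh import AtrialMesh, read_mesh, vertex_normals
from .resample import ResampleSpec, resample_mesh

__all__ = [
    "VoltageMap",
    "HistogramSpec",
    "AmplitudeHistogram",
    "LaseResult",
    "LvaRegion",
    "PipelineError",
    "peak_to_peak",
    "voltage_map",
    "amplitude_histogram",
    "shannon_entropy",
    "detect_lva",
    "classify_substrate",
    "lase_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# peak-to-peak and voltage map


def peak_to_peak(trace: np.ndarray) -> float:
    """Amplitude range ``max - min`` of a trace (same units as the trace)."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(trace)):
        raise ValueError("non-finite samples in trace")
    return float(trace.max() - trace.min())


@dataclass
class VoltageMap:
    """Per-vertex mean peak-to-peak amplitude in a.u.; invalid where |N_v|=0."""

    amplitude_au: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude_au = np.asarray(self.amplitude_au, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.amplitude_au.shape != self.valid.shape:
            raise ValueError("amplitude and validity arrays differ in length")

    @property
    def amplitude_mv(self) -> np.ndarray:
        return self.amplitude_au * MV_PER_AU

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_vertices(self) -> int:
        return len(self.valid)


def voltage_map(
    mesh: AtrialMesh,
    nset: NeighborSet,
    points: list[EgmPoint],
    noise_threshold_mv: float | None = None,
) -> VoltageMap:
    """Mean peak-to-peak amplitude over each vertex's neighborhood.

    When ``noise_threshold_mv`` is set, traces whose peak-to-peak exceeds
    it are dropped from the averaging (a vertex left with no usable
    neighbor becomes invalid).
    """
    if nset.n_vertices != mesh.n_vertices:
        raise ValueError("neighbor set does not match mesh")
    pp = np.array([peak_to_peak(p.trace) for p in points]) if points else np.empty(0)
    usable = np.ones(len(pp), dtype=bool)
    if noise_threshold_mv is not None and len(pp):
        usable = pp * MV_PER_AU <= noise_threshold_mv
    amp = np.zeros(mesh.n_vertices)
    valid = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        idx = nset[v]
        if len(idx) == 0:
            continue
        idx = idx[usable[idx]]
        if len(idx) == 0:
            continue
        amp[v] = pp[idx].mean()
        valid[v] = True
    return VoltageMap(amp, valid)


# ---------------------------------------------------------------------------
# histogram and entropy


@dataclass
class HistogramSpec:
    """Binning and entropy conventions.

    ``bin_width_au`` defaults to 100 a.u. = 0.3 mV at the 0.003 mV/a.u.
    conversion; ``origin_au`` anchors the first bin (``w0``, default 0).
    """

    bin_width_au: float = 100.0
    origin_au: float = 0.0
    entropy_mode: str = "plain"
    log_base: str = "2"
    denominator: str = "valid"
    au_to_mv: float = MV_PER_AU

    def __post_init__(self) -> None:
        if self.bin_width_au <= 0:
            raise ValueError("bin_width_au must be positive")
        if self.origin_au < 0:
            raise ValueError("origin_au must be >= 0")
        if self.entropy_mode not in ("plain", "width_corrected"):
            raise ValueError(f"unknown entropy_mode {self.entropy_mode!r}")
        if self.log_base not in ("2", "e"):
            raise ValueError("log_base must be '2' or 'e'")
        if self.denominator not in ("valid", "all"):
            raise ValueError("denominator must be 'valid' or 'all'")

    @property
    def bin_width_mv(self) -> float:
        return self.bin_width_au * self.au_to_mv

    def log(self, x):
        return np.log2(x) if self.log_base == "2" else np.log(x)

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "HistogramSpec":
        return cls(
            bin_width_au=cfg.bin_width_au,
            origin_au=cfg.w0,
            entropy_mode=cfg.entropy_mode,
            log_base=cfg.log_base,
            denominator=cfg.denominator,
            au_to_mv=cfg.au_to_mv,
        )


@dataclass
class AmplitudeHistogram:
    """Half-open bins ``[w0 + w*i, w0 + w*(i+1))`` with counts and p_i."""

    edges: np.ndarray
    counts: np.ndarray
    p: np.ndarray
    n_valid: int
    n_total: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def amplitude_histogram(vmap: VoltageMap, spec: HistogramSpec | None = None) -> AmplitudeHistogram:
    """Bin the valid per-vertex amplitudes; trailing empty bins trimmed."""
    spec = spec or HistogramSpec()
    values = vmap.amplitude_au[vmap.valid]
    if values.size == 0:
        raise ValueError("empty voltage map")
    if np.any(values < spec.origin_au):
        raise ValueError("amplitude below histogram origin w0")
    w = spec.bin_width_au
    idx = np.floor((values - spec.origin_au) / w).astype(np.int64)
    i0, i1 = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - i0, minlength=i1 - i0 + 1)
    denominator = vmap.n_vertices if spec.denominator == "all" else len(values)
    p = counts / denominator
    # empty bins outside the occupied range are trimmed; edges stay on the
    # w0-anchored grid
    edges = spec.origin_au + w * np.arange(i0, i1 + 2)
    return AmplitudeHistogram(
        edges=edges,
        counts=counts,
        p=p,
        n_valid=len(values),
        n_total=vmap.n_vertices,
    )


@dataclass
class LaseResult:
    """The entropy score plus everything needed to audit it."""

    entropy: float
    mode: str
    log_base: str
    histogram: AmplitudeHistogram
    n_excluded_vertices: int
    config: dict = field(default_factory=dict)
    lva: list = field(default_factory=list)
    coverage: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        hist = self.histogram
        return {
            "entropy_bits" if self.log_base == "2" else "entropy_nats": round(self.entropy, 9),
            "mode": self.mode,
            "bin_width_au": float(hist.edges[1] - hist.edges[0]),
            "bin_width_mv": round(float(hist.edges[1] - hist.edges[0]) * MV_PER_AU, 9),
            "w0": float(hist.edges[0]),
            "bins": [
                {
                    "lo": round(float(hist.edges[i]), 9),
                    "hi": round(float(hist.edges[i + 1]), 9),
                    "count": int(hist.counts[i]),
                    "p": round(float(hist.p[i]), 12),
                }
                for i in range(hist.n_bins)
            ],
            "excluded_vertices": self.n_excluded_vertices,
            "lva": [
                {
                    "n_vertices": r.n_vertices,
                    "area_cm2": round(r.area_cm2, 6),
                    "mean_amplitude_mv": round(r.mean_amplitude_mv, 6),
                }
                for r in self.lva
            ],
            "coverage": self.coverage,
            "config_hash": self.config.get("hash", ""),
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def shannon_entropy(hist: AmplitudeHistogram, spec: HistogramSpec | None = None) -> LaseResult:
    """Shannon entropy of the amplitude histogram.

    Plain mode: ``H = -sum p_i log(p_i)`` over non-zero bins.  Width
    corrected mode adds ``-log(w_mV)`` (at the default 0.3 mV bins and
    base 2 that is +1.737 bits).  A single-bin histogram legally yields
    H = 0 in plain mode.
    """
    spec = spec or HistogramSpec()
    p = hist.p[hist.p > 0]
    h = float(-(p * spec.log(p)).sum())
    if spec.entropy_mode == "width_corrected":
        h = h - float(spec.log(spec.bin_width_mv))
    return LaseResult(
        entropy=h,
        mode=spec.entropy_mode,
        log_base=spec.log_base,
        histogram=hist,
        n_excluded_vertices=hist.n_total - hist.n_valid,
    )


# ---------------------------------------------------------------------------
# low-voltage areas and classification


@dataclass
class LvaRegion:
    """A connected low-voltage region of the mesh."""

    vertices: np.ndarray
    area_cm2: float
    mean_amplitude_mv: float

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def detect_lva(
    vmap: VoltageMap,
    mesh: AtrialMesh,
    threshold_mv: float = 0.5,
    min_points: int = 5,
) -> list[LvaRegion]:
    """Connected components of valid vertices below ``threshold_mv``.

    Adjacency is mesh-edge connectivity.  Components with fewer than
    ``min_points`` members are discarded.  The region area is the summed
    area (cm^2) of faces whose three corners are all members.
    """
    if vmap.n_vertices != mesh.n_vertices:
        raise ValueError("voltage map does not match mesh")
    member = vmap.valid & (vmap.amplitude_mv < threshold_mv)
    if not member.any():
        return []
    edges = mesh.edges()
    keep = member[edges[:, 0]] & member[edges[:, 1]]
    e = edges[keep]
    n = mesh.n_vertices
    graph = coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    )
    n_comp, labels = connected_components(graph, directed=False)
    face_areas = mesh.face_areas()
    face_member = member[mesh.faces].all(axis=1)
    regions = []
    for comp in range(n_comp):
        verts = np.flatnonzero((labels == comp) & member)
        if len(verts) < min_points:
            continue
        comp_faces = face_member & np.isin(mesh.faces, verts).all(axis=1)
        area_mm2 = float(face_areas[comp_faces].sum())
        regions.append(
            LvaRegion(
                vertices=verts,
                area_cm2=area_mm2 / 100.0,
                mean_amplitude_mv=float(vmap.amplitude_mv[verts].mean()),
            )
        )
    regions.sort(key=lambda r: r.n_vertices, reverse=True)
    return regions


def classify_substrate(lase: "LaseResult | float", cutoff: float = 6.06) -> str:
    """``"abnormal"`` iff the entropy is strictly below ``cutoff``."""
    h = lase.entropy if isinstance(lase, LaseResult) else float(lase)
    return "abnormal" if h < cutoff else "normal"


# ---------------------------------------------------------------------------
# end-to-end pipeline


def lase_pipeline(
    mesh_path: str | Path | AtrialMesh,
    points_path: str | Path | list[EgmPoint],
    config: RunConfig | None = None,
) -> LaseResult:
    """Full pipeline: read, resample, associate, map, bin, score.

    ``mesh_path`` / ``points_path`` may also be in-memory objects.  Every
    stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    cfg = config or RunConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(name, exc) from exc

    if isinstance(mesh_path, AtrialMesh):
        mesh = mesh_path
    else:
        mesh = _stage("read_mesh", read_mesh, mesh_path)
    if isinstance(points_path, list):
        points = points_path
    else:
        points = _stage("read_points", read_points, points_path)

    if cfg.resample:
        mesh = _stage(
            "resample",
            resample_mesh,
            mesh,
            ResampleSpec(target_vertices=cfg.target_vertices, tolerance=cfg.tolerance),
        )
    normals = _stage("normals", vertex_normals, mesh)
    nset = _stage(
        "associate",
        associate,
        mesh,
        normals,
        points,
        AssociationSpec(sphere_radius=cfg.sphere_mm, cylinder_radius=cfg.cylinder_mm),
    )
    vmap = _stage(
        "voltage_map", voltage_map, mesh, nset, points, cfg.noise_threshold_mv
    )
    hspec = HistogramSpec.from_config(cfg)
    hist = _stage("histogram", amplitude_histogram, vmap, hspec)
    result = _stage("entropy", shannon_entropy, hist, hspec)
    result.lva = _stage(
        "lva", detect_lva, vmap, mesh, cfg.lva_threshold_mv, cfg.lva_min_points
    )
    result.coverage = coverage_report(nset)
    result.config = {**cfg.to_dict(), "hash": cfg.hash()}
    return result
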