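"""Virtual left atria for testing the whole pipeline without clinical data.

The generator produces the three ingredients the pipeline consumes:

* a closed, roughly ellipsoidal atrial shell (semi-axes ~35 x 30 x 25 mm)
  with smooth seeded bumps, triangulated near-uniformly at a requested
  vertex count;
* a per-vertex "true" bipolar amplitude field: spatially smooth
  log-normal healthy tissue (median 1.8 mV) with a configurable fraction
  of the surface covered by contiguous low-voltage patches (median
  0.2 mV, sub-threshold essentially by construction);
* a cloud of EGM acquisition points sampled area-uniformly on the shell,
  jittered off-surface along the local normal to mimic wall motion, each
  carrying a 2.5-s synthetic bipolar deflection train whose peak-to-peak
  amplitude equals the local true amplitude times a beat-to-beat
  multiplicative noise (CV 10% in sinus rhythm, inflated under AF) plus
  an additive noise floor.

Amplitude fields are log-Gaussian random fields (sum-of-random-cosines
construction), not independent per-vertex draws: real voltage maps are
spatially coherent, and coherence is what keeps neighbor averaging from
shrinking the amplitude distribution.  Trace morphology is cosmetic —
only the peak-to-peak matters downstream — so fidelity is guaranteed on
the peak-to-peak (exact up to float rounding) rather than on waveform
shape.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .association import AU_PER_MV, EgmPoint, TRACE_DURATION_S
from .mesh import AtrialMesh
from .resample import ResampleSpec, resample_mesh

__all__ = [
    "SubstrateModel",
    "SimulationSpec",
    "CohortSubject",
    "make_atrium_mesh",
    "paint_substrate",
    "sample_egm_points",
    "make_cohort",
]


@dataclass
class SubstrateModel:
    """Spatial substrate: healthy tissue plus low-voltage patches.

    ``lva_fraction`` is the fraction of surface area covered by patches.
    Healthy amplitudes are log-normal with median 1.8 mV and log-sd 0.7
    (putting roughly P5 at 0.6 mV and P95 at 6 mV, the dispersion seen in
    normal-atrium bipolar maps); patch amplitudes are log-normal with
    median 0.2 mV and log-sd 0.3, i.e. below the 0.5 mV scar threshold
    for ~99.9% of patch tissue.  ``af_amplitude_cv`` inflates the
    beat-to-beat multiplicative variability when the rhythm is AF.
    """

    lva_fraction: float = 0.0
    n_patches: int = 3
    healthy_median_mv: float = 1.8
    healthy_sigma_log: float = 0.7
    lva_median_mv: float = 0.2
    lva_sigma_log: float = 0.3
    rhythm: str = "SR"
    af_amplitude_cv: float = 0.5
    base_cv: float = 0.10
    correlation_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lva_fraction <= 1.0:
            raise ValueError("lva_fraction must be in [0, 1]")
        if self.healthy_median_mv <= 0 or self.lva_median_mv <= 0:
            raise ValueError("medians must be positive")
        if self.lva_median_mv >= 0.5:
            raise ValueError("lva median must stay below the 0.5 mV threshold")
        if self.rhythm not in ("SR", "AF"):
            raise ValueError("rhythm must be 'SR' or 'AF'")
        if self.lva_fraction > 0 and self.n_patches <= 0:
            raise ValueError("lva_fraction > 0 requires n_patches >= 1")

    @property
    def beat_cv(self) -> float:
        """Multiplicative beat-to-beat CV of the emitted peak-to-peak."""
        if self.rhythm == "AF":
            return self.base_cv * (1.0 + self.af_amplitude_cv)
        return self.base_cv


@dataclass
class SimulationSpec:
    """Scale and acquisition parameters of one virtual subject."""

    n_mesh_vertices: int = 2000
    n_points: int = 3000
    seed: int = 0
    sample_rate: float = 1000.0
    noise_floor_mv: float = 0.05
    semi_axes_mm: tuple = (35.0, 30.0, 25.0)
    jitter_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.n_mesh_vertices < 100:
            raise ValueError("n_mesh_vertices must be >= 100")
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_floor_mv < 0:
            raise ValueError("noise_floor_mv must be >= 0")


# ---------------------------------------------------------------------------
# geometry


_ICOSPHERE_COUNTS = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562, 5: 10242, 6: 40962}


def make_atrium_mesh(spec: SimulationSpec) -> AtrialMesh:
    """A closed bumpy-ellipsoid shell at the requested vertex count (+/-2%)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_mesh_vertices
    sub = min(_ICOSPHERE_COUNTS, key=lambda k: abs(_ICOSPHERE_COUNTS[k] - n))
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    faces = np.asarray(ico.faces, dtype=np.int64)

    # smooth seeded bumps on the unit sphere: radial scaling by a small
    # sum of von-Mises-like lobes keeps the shape star-shaped
    n_lobes = 6
    dirs = rng.normal(size=(n_lobes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.normal(0.0, 0.04, size=n_lobes)
    kappa = 6.0
    radial = 1.0 + (amps * np.exp(kappa * (verts @ dirs.T - 1.0))).sum(axis=1)
    radial = np.clip(radial, 0.7, 1.3)
    verts = verts * radial[:, None] * np.asarray(spec.semi_axes_mm)

    mesh = AtrialMesh(verts, faces)
    tol = max(2, int(round(0.02 * n)))
    if abs(mesh.n_vertices - n) > tol:
        mesh = resample_mesh(
            mesh, ResampleSpec(target_vertices=n, tolerance=tol, area_tolerance=None)
        )
    return mesh.validate()


# ---------------------------------------------------------------------------
# substrate


def _random_cosine_field(rng: np.random.Generator, corr_mm: float, n_terms: int = 48):
    """A ~N(0,1) smooth random field on R^3 as a sum of random cosines."""
    k = rng.normal(scale=2.0 * np.pi / corr_mm / np.sqrt(3.0), size=(n_terms, 3))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_terms)
    scale = np.sqrt(2.0 / n_terms)

    def evaluate(x: np.ndarray) -> np.ndarray:
        return scale * np.cos(x @ k.T + phase).sum(axis=1)

    return evaluate


def _vertex_areas(mesh: AtrialMesh) -> np.ndarray:
    fa = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], fa / 3.0)
    return va


def paint_substrate(
    mesh: AtrialMesh, model: SubstrateModel, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex true amplitude field (mV) and ground-truth patch mask.

    Patches are grown from ``n_patches`` random seed vertices by
    multi-source breadth-first dilation over mesh edges until the covered
    area fraction reaches ``lva_fraction`` (to within one vertex area).
    Returns ``(amplitude_mv, lva_mask)``.
    """
    mesh.validate()
    rng = np.random.default_rng(seed)
    healthy_field = _random_cosine_field(rng, model.correlation_mm)
    lva_field = _random_cosine_field(rng, model.correlation_mm)

    v = mesh.vertices
    healthy = model.healthy_median_mv * np.exp(
        model.healthy_sigma_log * healthy_field(v)
    )
    lva_amp = model.lva_median_mv * np.exp(model.lva_sigma_log * lva_field(v))

    mask = np.zeros(mesh.n_vertices, dtype=bool)
    if model.lva_fraction > 0:
        areas = _vertex_areas(mesh)
        total = areas.sum()
        target = model.lva_fraction * total
        adj = mesh.vertex_adjacency()
        seeds = rng.choice(mesh.n_vertices, size=min(model.n_patches, mesh.n_vertices), replace=False)
        queue = deque(int(s) for s in seeds)
        covered = 0.0
        while queue and covered < target:
            u = queue.popleft()
            if mask[u]:
                continue
            mask[u] = True
            covered += areas[u]
            for nb in sorted(adj[u]):
                if not mask[nb]:
                    queue.append(nb)
    amplitude = np.where(mask, lva_amp, healthy)
    return amplitude, mask


# ---------------------------------------------------------------------------
# EGM sampling


def _beat_template(sample_rate: float) -> np.ndarray:
    """Unit biphasic deflection (Gaussian first derivative, ~40 ms wide)."""
    half = int(round(0.02 * sample_rate))
    t = np.arange(-3 * half, 3 * half + 1) / max(half, 1)
    w = -t * np.exp(-0.5 * t**2)
    return w / (w.max() - w.min())


def sample_egm_points(
    mesh: AtrialMesh,
    amplitude_mv: np.ndarray,
    spec: SimulationSpec,
    model: SubstrateModel,
    seed: int | None = None,
) -> list[EgmPoint]:
    """Sample ``n_points`` acquisition sites with synthetic 2.5-s traces.

    Sites are area-uniform on the surface, displaced up to
    ``jitter_mm`` along the local face normal.  Each trace is rescaled so
    its peak-to-peak equals the target amplitude exactly (local true
    amplitude x multiplicative beat noise + noise floor), in a.u.
    """
    mesh.validate()
    amplitude_mv = np.asarray(amplitude_mv, dtype=float)
    if amplitude_mv.shape != (mesh.n_vertices,):
        raise ValueError("amplitude field does not match mesh")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_points
    if n == 0:
        return []

    fa = mesh.face_areas()
    fidx = rng.choice(len(fa), size=n, p=fa / fa.sum())
    r1 = np.sqrt(rng.uniform(size=n))
    r2 = rng.uniform(size=n)
    tri = mesh.vertices[mesh.faces[fidx]]
    bary = np.stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2], axis=1)
    surf = np.einsum("ij,ijk->ik", bary, tri)

    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    jitter = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=n)
    positions = surf + jitter[:, None] * fn

    # local truth: amplitude of the nearest face corner
    corner = np.argmax(bary, axis=1)
    local_amp = amplitude_mv[mesh.faces[fidx, corner]]

    cv = model.beat_cv
    mult = np.exp(rng.normal(0.0, cv, size=n))
    target_mv = local_amp * mult + spec.noise_floor_mv
    target_au = target_mv * AU_PER_MV

    n_samples = int(round(TRACE_DURATION_S * spec.sample_rate))
    template = _beat_template(spec.sample_rate)
    half_len = len(template)
    wiggle = rng.normal(0.0, 0.02, size=(n, n_samples))
    traces = wiggle.copy()
    beat_interval = rng.uniform(0.55, 0.85, size=n)  # ~70-110 bpm
    phase = rng.uniform(0.0, 1.0, size=n)
    for i in range(n):
        step = beat_interval[i] * spec.sample_rate
        starts = np.arange(phase[i] * step, n_samples - half_len, step).astype(int)
        beat_amp = 1.0 + rng.normal(0.0, 0.1, size=len(starts))
        for s, a in zip(starts, beat_amp):
            traces[i, s : s + half_len] += a * template
    ptp = traces.max(axis=1) - traces.min(axis=1)
    traces *= (target_au / ptp)[:, None]

    return [
        EgmPoint(
            point_id=f"p{i:05d}",
            position=positions[i],
            trace=traces[i],
            sample_rate=spec.sample_rate,
        ).validate()
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSubject:
    """One virtual patient with full ground truth."""

    subject_id: int
    substrate: str
    lva_fraction: float
    rhythm: str
    mesh: AtrialMesh
    points: list[EgmPoint]
    amplitude_mv: np.ndarray = field(repr=False, default=None)
    lva_mask: np.ndarray = field(repr=False, default=None)
    seed: int = 0


def make_cohort(
    n_normal: int,
    n_abnormal: int,
    spec: SimulationSpec | None = None,
    seed: int = 0,
    model: SubstrateModel | None = None,
) -> list[CohortSubject]:
    """A cohort of virtual subjects with recorded ground truth.

    Normal subjects carry an LVA burden of at most 2% of the surface;
    abnormal subjects draw their burden uniformly from 15-30%, the range
    reported for persistent-AF atria.  Rhythm during acquisition is SR
    with probability 0.7 (normal) / 0.2 (abnormal).
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("cohort counts must be >= 0")
    spec = spec or SimulationSpec()
    base_model = model or SubstrateModel()
    rng = np.random.default_rng(seed)
    subjects = []
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    for i, label in enumerate(labels):
        sub_seed = int(rng.integers(0, 2**31 - 3))
        sub_rng = np.random.default_rng(sub_seed)
        if label == "normal":
            frac = float(sub_rng.uniform(0.0, 0.02))
            n_patches = int(sub_rng.integers(1, 3)) if frac > 0 else 0
            rhythm = "SR" if sub_rng.uniform() < 0.7 else "AF"
        else:
            frac = float(sub_rng.uniform(0.15, 0.30))
            n_patches = int(sub_rng.integers(2, 5))
            rhythm = "SR" if sub_rng.uniform() < 0.2 else "AF"
        sub_model = SubstrateModel(
            lva_fraction=frac,
            n_patches=max(n_patches, 1) if frac > 0 else 0,
            healthy_median_mv=base_model.healthy_median_mv,
            healthy_sigma_log=base_model.healthy_sigma_log,
            lva_median_mv=base_model.lva_median_mv,
            lva_sigma_log=base_model.lva_sigma_log,
            rhythm=rhythm,
            af_amplitude_cv=base_model.af_amplitude_cv,
            base_cv=base_model.base_cv,
            correlation_mm=base_model.correlation_mm,
        )
        sub_spec = SimulationSpec(
            n_mesh_vertices=spec.n_mesh_vertices,
            n_points=spec.n_points,
            seed=sub_seed,
            sample_rate=spec.sample_rate,
            noise_floor_mv=spec.noise_floor_mv,
            semi_axes_mm=spec.semi_axes_mm,
            jitter_mm=spec.jitter_mm,
        )
        mesh = make_atrium_mesh(sub_spec)
        amp, mask = paint_substrate(mesh, sub_model, seed=sub_seed + 1)
        points = sample_egm_points(mesh, amp, sub_spec, sub_model, seed=sub_seed + 2)
        subjects.append(
            CohortSubject(
                subject_id=i,
                substrate=label,
                lva_fraction=frac,
                rhythm=rhythm,
                mesh=mesh,
                points=points,
                amplitude_mv=amp,
                lva_mask=mask,
                seed=sub_seed,
            )
        )
    return subjects
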