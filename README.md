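# lase — left atrial spatial entropy

Tools for characterizing the left atrial (LA) electrical substrate from
bipolar electroanatomic voltage maps, for cardiac electrophysiologists and
signal-processing researchers working with atrial fibrillation (AF)
ablation data.

Conventional substrate assessment thresholds the bipolar voltage map
(low-voltage areas, LVA: ≥5 adjacent sites < 0.5 mV) and is sensitive to
rhythm, wavefront direction and arbitrary cutoffs.  **Left atrial spatial
entropy (LASE)** instead summarizes the *whole distribution* of voltage
over the chamber in a single score.  Given a triangulated LA surface with
vertex set *V* and a cloud of electrogram (EGM) recordings, the pipeline:

1. resamples the mesh to a standard 5,000 ± 100 vertices (edge
   collapse/split), so scores are comparable across patients;
2. computes outward vertex normals and associates each vertex *v* with
   the EGM points `N_v` lying inside an 8 mm sphere around *v* **and**
   within 2 mm of the normal line (a capped cylinder, tolerant of wall
   motion);
3. assigns each vertex the mean peak-to-peak amplitude of its
   neighborhood,
   `a(v) = (1/|N_v|) Σ_{n∈N_v} (max xₙ − min xₙ)`,
   where `xₙ` is the 2.5-s bipolar trace at point *n*;
4. bins `{a(v)}` at width *w* = 100 a.u. = 0.3 mV (0.003 mV/a.u.) from
   origin `w₀` and computes the Shannon entropy

   `H = − Σᵢ pᵢ log₂ pᵢ`,  `pᵢ = #{v : w₀+w(i−1) ≤ a(v) < w₀+wi} / #V`.

A homogeneous, healthy substrate spreads amplitude over many bins
(high *H*); fibrotic, patchy substrate concentrates it (low *H*).  On the
bundled 27-patient cohort table the score separates paroxysmal from
persistent AF and normal from abnormal substrate, independent of the
rhythm during acquisition, with low scores classified as abnormal below a
Youden-index cutoff.

The package also ships the validation layer (Bland–Altman agreement, ROC
with Youden cutoff, one-tailed *t*-tests, Cohen's kappa) and a synthetic
atrium generator (bumpy ellipsoidal shells, spatially coherent log-normal
amplitude fields, controllable LVA burden, rhythm-dependent beat-to-beat
variability) so every stage is testable without clinical data.

## Worked example

```python
from lase import RunConfig, lase_pipeline, classify_substrate
from lase.synthetic import (SimulationSpec, SubstrateModel, make_atrium_mesh,
                            paint_substrate, sample_egm_points)

spec = SimulationSpec(n_mesh_vertices=800, n_points=3000, seed=7)
mesh = make_atrium_mesh(spec)
for name, model in [
    ("homogeneous", SubstrateModel()),
    ("patchy (25% LVA)", SubstrateModel(lva_fraction=0.25, n_patches=3)),
]:
    amplitude, _ = paint_substrate(mesh, model, seed=7)
    points = sample_egm_points(mesh, amplitude, spec, model, seed=8)
    result = lase_pipeline(mesh, points, RunConfig(resample=False))
    lva_area = sum(r.area_cm2 for r in result.lva)
    print(f"{name:17s} H = {result.entropy:.3f} bits  "
          f"({classify_substrate(result, cutoff=4.03)})  "
          f"LVA: {len(result.lva)} regions, {lva_area:.1f} cm^2")
```

prints

```
homogeneous       H = 4.187 bits  (normal)  LVA: 0 regions, 0.0 cm^2
patchy (25% LVA)  H = 4.015 bits  (abnormal)  LVA: 3 regions, 18.1 cm^2
```

The homogeneous substrate scores the higher entropy; painting a quarter of
the surface with sub-0.5 mV patches lowers it by ~0.17 bits and the
low-voltage detector finds the three painted regions (≈18 cm²).  The 4.03
cutoff is the Youden cutoff of the synthetic cohort at this problem size;
clinical-scale maps use the clinical cutoff (default 6.06).

The same pipeline is available from the shell:

```sh
lase synth --subjects 27 --abnormal 10 --seed 0 --out cohort/
lase compute --mesh cohort/subject_000.ply --points cohort/subject_000.csv \
     --target-vertices 5000 --out result.json
lase stats --report cohort_stats.json   # bundled 27-patient table
lase report --result result.json
```

Meshes are read/written as PLY (ascii or binary little-endian), OFF and
legacy-VTK polydata; EGM points use a documented CSV/JSON interchange
format (`point_id,x_mm,y_mm,z_mm,sample_rate_hz,s0..sN`).

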