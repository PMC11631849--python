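# Methods

## The score

LASE treats an electroanatomic voltage map as a probability distribution.
The spatial domain is the vertex set of the LA surface mesh; the measured
quantity at a vertex is the mean peak-to-peak (PP) bipolar amplitude of
the EGM recordings associated with it; the score is the Shannon entropy of
the binned distribution of those per-vertex amplitudes.  Entropy is
maximal when every amplitude bin is equally likely (uniformly heterogeneous
amplitudes across the chamber, the signature of healthy tissue in this
framework) and falls as probability mass concentrates — which is what
confluent low-voltage regions do to the histogram.

The entropy is reported in bits (base-2 log; base-e available).  Two modes
are implemented because the bin width can enter the formula in two ways:

* `plain` (default): `H = −Σ pᵢ log₂ pᵢ`;
* `width_corrected`: adds `−log₂(w_mV)` (+1.737 bits at w = 0.3 mV), a
  density-style correction.

Both differ by a constant at fixed bin width, so every comparison, ROC or
rank statistic is mode-invariant.  The default bin width is 100 a.u. =
0.3 mV (conversion 0.003 mV/a.u.), the amplitude scale at which scar
discriminates best from surrounding myocardium; the histogram origin `w₀`
defaults to 0.

Vertices whose neighborhood is empty carry no amplitude; by default they
are excluded from the histogram denominator (`denominator="valid"`), and
their count is reported.  The literal all-vertex denominator is available
(`denominator="all"`) but makes the "probabilities" sum to the mapped
fraction rather than 1.

A trace-level noise gate (`noise_threshold_mv`) can exclude recordings
whose PP exceeds a threshold (3.5 mV is the conventional value) from the
neighborhood averages.  It is **off by default**: per-patient entropies of
4.5–7.2 bits, as observed clinically, are arithmetically impossible when
amplitudes are capped at 3.5 mV with 0.3 mV bins (at most
log₂(3.5/0.3) ≈ 3.5 bits plain), so the gate cannot have been part of the
entropy computation that produced such values; it is provided for
sensitivity analyses.

## Geometry

**Vertex normals** are the normalized area-weighted mean of incident face
normals (area weighting is the common default; uniform weighting is a
config option).  Orientation is resolved globally by the centroid test:
if normals on average point toward the surface centroid, the whole field
is flipped.  This is exact for star-shaped chambers — a safe assumption
for atrial shells — and is a documented limitation for pathological
geometries.

**Point association** attributes an EGM point to a vertex when it lies
within 8 mm of the vertex (sphere) and within 2 mm of the infinite line
through the vertex along its normal (cylinder).  Both tests are inclusive
at the boundary, which makes the result permutation-stable and exactly
reproducible.  No half-space restriction is applied: recordings displaced
to either side of the reconstructed surface by wall motion are kept, which
is the stated motivation for the cylinder construction.  A point may
belong to several vertices; no deduplication is performed.  A KD-tree
accelerates the sphere stage, but the contract (enforced by test) is exact
set-equality with the brute-force double loop.

**Resampling** standardizes the vertex count (default 5,000 ± 100).
Downsampling collapses the globally shortest edge to its midpoint;
upsampling splits the globally longest edge at its midpoint.  Processing
in strict length order via a lazy heap is the limiting case of a
collapse/split threshold scheme — the implicit threshold is the k-th
order statistic of the edge-length distribution — and lands the count
exactly on target in one monotone pass.  A collapse is skipped when it
would violate the edge link condition (non-manifold fin).  After
splitting, a guarded edge-flip pass restores triangle quality (local
Delaunay-style flips restricted to face pairs within 20° of coplanarity,
so the geometry is not disturbed).  Midpoint splits preserve area exactly;
collapses on a dense smooth shell change it by well under the 2% contract,
which is checked on closed inputs and raises on violation.  Measured
drifts on test shells are below 0.1% across the 500→5,000 and
20,000→5,000 paths.

**Low-voltage areas** are connected components (mesh-edge adjacency) of
valid vertices below 0.5 mV with at least 5 members; the clinical
definition counts adjacent catheter *points*, and vertices are this
pipeline's native resolution, so the min-count applies to vertices.
Region area sums the faces whose three corners are members.

## Cohort statistics

* Bland–Altman: differences `a − b`, sample (n−1) SD, limits of agreement
  mean ± 1.96·SD.  The 1.96 multiplier is used because the bundled cohort
  table reproduces the published limits under it (a standard-error CI does
  not).
* Two-sample t: pooled-variance Student by default (Welch behind a flag),
  one-tailed.  Fully degenerate input (both variances zero, equal means)
  returns p = 0.5, flagged.
* ROC: AUC via the Mann–Whitney U equivalence (ties count ½); the Youden
  cutoff maximizes sensitivity + specificity − 1 over observed score
  thresholds, ties broken toward the lowest threshold (the more sensitive
  rule), with the low-score-positive orientation used by an entropy that
  falls with disease.
* Cohen's kappa with the convention κ = 1 for perfect agreement even when
  expected agreement is 1.

Recomputation of the bundled 27-patient table gives a substrate AUC of
0.94, group means 6.60 ± 0.38 (paroxysmal) vs 5.41 ± 0.46 (persistent) and
one-tailed p ≈ 5·10⁻⁸; these recomputed values are reported as such by
`cohort_report` and the acceptance script.  Only the Bland–Altman
quantities and the count-based claims reproduce published summaries
exactly; the implementations are therefore validated against independent
oracles (exhaustive pairwise AUC, closed-form t) rather than against
published summary statistics.  The Bland–Altman mean difference recomputes
to −0.3448 (published rounding: −0.35) with limits −0.805 / 0.115.

## Synthetic atria

The generator emulates the *statistics* a voltage-mapping pipeline sees,
not atrial electrophysiology:

* **Shape**: an icosphere warped by ≤6 smooth random radial lobes and
  scaled to semi-axes 35 × 30 × 25 mm (LA-sized), then resampled to the
  requested vertex count.  Closed, star-shaped, consistently wound.
* **Amplitude field**: log-normal, *spatially coherent* (a
  sum-of-random-cosines Gaussian field in log-amplitude, correlation
  length 10 mm).  Coherence matters: with independent per-vertex draws,
  neighborhood averaging would shrink the amplitude spread and bias the
  entropy down.  Healthy tissue: median 1.8 mV, log-SD 0.7, putting P5 at
  ≈0.6 mV and P95 at ≈6 mV — the dispersion reported for structurally
  normal atria; ~3% of healthy surface falls below 0.5 mV, as real
  "normal" maps do.  Patches: median 0.2 mV, log-SD 0.3, below the 0.5 mV
  threshold for ≈99.9% of patch area.
* **Patches** grow from random seed vertices by multi-source breadth-first
  dilation until the requested area fraction is covered; ground truth is
  returned.
* **Acquisition**: sites are area-uniform on the shell, jittered ≤1.5 mm
  along the local normal (wall-motion surrogate, safely inside the
  8 mm/2 mm association envelope).  Each 2.5-s trace is a biphasic
  deflection train at 70–110 bpm plus a small wiggle, rescaled so its PP
  equals the target exactly: local amplitude × a multiplicative beat
  factor (CV 10% in SR, ×1.5 under AF) + an additive 0.05 mV noise floor.
  Trace morphology is cosmetic; only the PP reaches the score, so fidelity
  is guaranteed on the PP.
* **Cohorts**: normal subjects draw an LVA burden ≤ 2% of the surface,
  abnormal subjects 15–30% (the burden range reported for persistent-AF
  atria); rhythm is SR with probability 0.7 / 0.2 respectively.

Everything is a pure function of (spec, seed).

What passing the synthetic tests does **not** show: realism of waveform
shape, far-field or fractionated electrograms, catheter-contact artifacts,
non-star-shaped anatomies (appendage, vein ostia), or the heavy amplitude
tails of clinical maps — clinical healthy-substrate entropies reach ≈6.4
bits, implying amplitude spreads far beyond a log-normal with the above
parameters, so absolute synthetic entropies (≈4 bits) sit below clinical
ones and cutoffs must be rescaled to problem size.

## Validation experiments and problem sizes

The end-to-end experiments (`lase.experiments`) run the full pipeline on
800-vertex shells at native resolution with ~3,000 acquisition sites — the
clinical site density, on a mesh scaled down from the clinical 5,000
vertices to keep the full battery within minutes on one CPU:

* **Matched pairs** (n = 100): homogeneous vs 30%-burden substrate sharing
  shell, healthy field and site seed.  The homogeneous member scores
  higher in 100/100 runs (gap 0.20 ± 0.05 bits).
* **Dose response**: mean entropy over burdens {0, 0.1, 0.2, 0.3, 0.4}
  (8 shells per level).  The curve falls from ≈4.05 to ≈3.62 bits with a
  small rise (+0.06) at burden 0.1; Spearman ρ of the curve is −0.90
  (pooled per-run ρ ≈ −0.75; both are reported).  The initial rise is a
  real property of mixture entropy: adding a small disjoint mode *raises*
  entropy until the mixing term `h_b(f)` is outweighed by the
  entropy-contrast term `f·(H_healthy − H_lva)`.
* **Cohort discrimination**: 17 normal / 10 abnormal subjects,
  replicate-averaged over 6 cohorts.  Measured AUC ≈ 0.74–0.82 depending
  on seed.  This is a known, structural limitation at these study
  conditions: with healthy binned entropy ≈4.1 bits and patch entropy
  ≈0.5 bits, burdens near 0.15 produce entropies at or above homogeneous
  maps (the same `h_b(f)` mechanism), so abnormal subjects at the low end
  of the 15–30% range are not separable and the attainable AUC sits near
  0.8.  Clinical maps, with their much broader healthy amplitude spread
  (H ≈ 6.4 bits), do not hit this ceiling.

## Numerical conventions

Distances in mm, amplitudes in a.u. (0.003 mV/a.u.), areas in cm² at the
reporting surface.  Histogram bins are half-open `[lo, hi)` on the
`w₀`-anchored grid with leading/trailing empty bins trimmed.  Association
boundaries are inclusive.  Classification is abnormal iff H is strictly
below the cutoff (default 6.06 at clinical scale), so a score exactly at
the cutoff is normal.  Result JSON is emitted with sorted keys and
fixed-precision floats, so identical inputs and config produce identical
bytes.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.
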