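# Methods

## Model and procedure

tofsig maps the arterial wall of a 3D TOF-MRA volume and assigns every wall
point a signal-intensity gradient (SIG, SI/mm), a surrogate for wall shear
stress. The chain is:

1. **World frame.** Voxel indices (i, j, k) map affinely to mm positions
   `spacing · (index − center_index)` with `center_index = (N−1)/2` per
   axis, so the volume center is the world origin for odd and even grid
   sizes alike. Axes are right-handed, i→x, j→y, k→z; only axis-aligned
   axial acquisitions are accepted (oblique DICOM orientations are
   rejected, not reinterpreted).
2. **Normalization.** Φ = (φ − μ)/σ with the *population* standard
   deviation, by default over the whole volume (an optional mask can
   restrict the statistics to tissue). The z-score makes SIG invariant to
   scanner offset/scale: normalize(aφ + b) = normalize(φ) for a > 0.
3. **Wall extraction.** The wall is the iso-value level set, triangulated
   by 3D marching cubes; per-slice isolines are available for source-image
   overlays. Every vertex lies on a grid edge, where trilinear
   interpolation is linear, so the level-set property
   |trilinear(X) − iso| ≈ 0 holds at vertices. Morphological noise
   rejection runs in the voxel domain before meshing (face-connected
   supra-threshold components below a size cutoff are suppressed; face
   connectivity matches the topology marching cubes actually produces) and
   optionally on the mesh (small vertex-connected components dropped).
4. **SIG.** At each isopoint the grid gradient (spacing-aware central
   differences, one-sided at borders) is trilinearly interpolated and
   normalized to n = ∇Φ/‖∇Φ‖; the inner point is X_b = X_a + d·n; Φ_a and
   Φ_b are trilinear samples; SIG = (Φ_b − Φ_a)/d and the vector SIG is
   SIG·n. Points with ‖∇Φ‖ ≤ ε (default 1e−8 on the normalized scale) or
   with X_a/X_b outside the voxel-center box are flagged, excluded from
   summaries and counted in the run report — never silently dropped.
5. **Evaluation sampling.** Cross-section planes perpendicular to a
   user-supplied vessel axis (the axis is an input, matching how levels
   are chosen anatomically; no centerline detection) at a fixed spacing,
   each sampled at equally spaced azimuths from a reference direction.
   Each (level, site) takes the wall point nearest the site's radial ray,
   restricted to a slab of half-width spacing/2; ties break by smallest
   distance, then lexicographic position, which keeps the output invariant
   to wall-point ordering. Group contrasts use Welch's t (no
   equal-variance assumption); agreement with a reference map uses
   Pearson's r.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| offset d | 0.03 | mm | inner-point distance; small enough to stay inside one voxel, large enough for a stable difference quotient |
| flat-field ε | 1e−8 | normalized SI | gradient magnitude below which no direction exists |
| iso value | user / suggested | SI | wall threshold; the suggester lowers Otsu's split to the smallest value keeping the vessel a single component, and only ever *reports* it |
| min component voxels | 27 | voxels | ≈ 3×3×3: smallest blob treated as signal rather than noise |
| levels × sites | 6 × 2.5 mm × 12 | — | cross-sectional evaluation design |

## The phantom generator

`phantom_synth` emulates the physics qualitatively, not mechanistically:
flow-related enhancement with peripheral intraluminal saturation is
modeled as a radial intensity profile Φ = background + A·f(r) + noise
around a tube axis. Two profiles: `plateau_sigmoid`
(f = 1/(1+exp((r−r₀)·flow_scale/w)), a bright plug-flow core with
sigmoidal wall falloff — the demo default) and `gaussian` (smooth
everywhere — the oracle-test default). `flow_scale` is an abstract flow
surrogate that steepens |dΦ/dr| at the wall monotonically; it is *not* a
calibrated map from L/min to intensity. Geometries: straight tube, two
parallel tubes, circular-arc (torus) tube; a straight tube can carry an
azimuthal amplitude modulation A(1 + m·cosθ) emulating the azimuthally
uneven saturation of curved vessels. Defaults mirror a pumped-tube MR
phantom: radius 10.5 mm (2.1 cm inner-diameter tubing), 0.5 mm isotropic
voxels, amplitude 100 over background 5 (≈ bright lumen over dim
background), edge width 1.2 mm, additive white Gaussian noise (Rician
realism is out of scope; normalization and gradient testing need a
symmetric baseline). Every volume is a pure function of (spec, seed), and
each spec's oracle evaluates Φ and ∇Φ in closed form at any position —
the ground truth for every pipeline stage.

What the phantoms do **not** contain: pulsatile flow, spin-history
effects, coil shading, Rician noise floors, wall motion, or realistic
carotid geometry. Passing phantom tests therefore demonstrates numerical
correctness of the estimator and the monotone flow→gradient→SIG chain, not
clinical accuracy on patient scans.

## Numerical choices and observed behavior

- **Gradient off-lattice.** Central differences on the grid, then
  trilinear interpolation of the three components — smooth, standard, and
  exact for affine fields. Near the volume border one-sided differences
  apply and accuracy degrades from O(h²) to O(h); wall points within a
  couple of voxels of the border should be read with that in mind.
- **Discretization floor.** At fixed spacing h the SIG error against the
  analytic gradient does not vanish as d → 0: it saturates at the error of
  the trilinear interpolant's directional derivative. On a Gaussian tube
  sampled at σ/4 the median relative error is ≈ 4% and falls roughly
  quadratically as the grid is refined (≈ 1.0% at σ/8, ≈ 0.6% at σ/16).
  The offset-d bias itself is monotone: on the analytic field the
  difference quotient converges to ‖∇Φ‖ as d shrinks through 0.3, 0.1,
  0.03 mm.
- **Statistics on sites, not vertices.** Neighboring mesh vertices
  interpolate from shared voxels, so vertex-level SIG values are spatially
  correlated; t-tests over all vertices would be anticonservative. The
  phantom experiment therefore tests the 6 × 12 sampled sites per tube,
  whose spacing makes them effectively independent (their null p-values
  are uniform in simulation).
- **Rotation robustness.** Rotating an azimuthally modulated phantom 30°
  about its axis changes the mean wall SIG by < 0.1%. Tilting the tube
  *axis* 30° within the slice plane changes it by ≈ 3.5% at 0.5 mm
  spacing with a 1.2 mm edge — the anisotropy of central differences on a
  steep edge; finer grids reduce it. The iso for modulated phantoms must
  sit below the lowest azimuthal peak or the level set pinches off at the
  dim side.
- **Threshold suggestion** is a documented heuristic (Otsu, then lower
  until the significant-component census changes under 26-connectivity or
  the foreground exceeds half the volume), reported with histogram
  diagnostics and never applied without the caller's consent; on weakly
  bimodal or constant data it returns a failure flag instead of a number.
- **Degenerate inputs** raise typed errors: zero variance (normalization),
  iso outside the data range (extraction), all components removed
  (cleanup), n < 2 per group (t-test), zero variance or n < 3
  (correlation), non-positive d or spacing (parameters).

## Problem sizes

Default phantom volumes are 64 × 64 × 36 voxels at 0.5 mm (≈ 150k voxels,
≈ 6–10k wall vertices); the convergence study refines a 20³-scale grid
twice to 80 × 80 × 50. These sizes resolve the wall with 2–3 voxels across
the falloff and give sub-second pipeline runs, so the whole verification
battery regenerates everything from scratch in seconds.

## Known limitations

- Axial, axis-aligned acquisitions only; no registration, bias-field
  correction, or oblique resampling.
- SIG is left in SI/mm; no viscosity calibration to physical WSS units.
- The vessel axis for cross-section sampling is user-supplied; no
  automatic centerline.
- The flow→intensity link in the phantoms is phenomenological; absolute
  SIG levels from phantoms should not be compared against patient-scan
  values.
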