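# tofsig

Arterial wall **signal-intensity-gradient (SIG)** mapping from time-of-flight
MR angiography (TOF-MRA) — a fast, per-vertex surrogate for wall shear
stress (WSS).

## The problem

Wall shear stress, the tangential stress blood flow exerts on the arterial
wall, is a key hemodynamic marker for vascular disease, but it is hard to
measure: CFD needs hours of simulation and carefully set boundary
conditions, and phase-contrast MR lacks resolution in the wall boundary
layer. TOF-MRA, in contrast, is acquired routinely. Its bright-blood signal
comes from flow-related enhancement: fresh spins entering the slab are
bright, while slow near-wall flow suffers intraluminal saturation. The
steepness of the intensity falloff across the wall therefore carries
flow-rate and geometry information, and its gradient can stand in for WSS —
computable from a standard scan in seconds.

## The method

Raw intensities φ are z-scored over the dataset, Φ = (φ − μ_φ)/σ_φ, to
remove scanner offset and scale. The arterial wall is the iso-intensity
surface of a chosen threshold ("isopoints" A at positions **X**_a, with the
volume's world frame centered so the middle of the volume maps to (0,0,0)).
At each isopoint the direction of maximum intensity increase is

    n = ∇Φ / ‖∇Φ‖,

an inner point B is placed at a fixed offset along it,

    X_b = X_a + d·n,          d = 0.03 mm,

and the scalar SIG is the difference quotient of the trilinearly
interpolated intensities,

    SIG = (Φ_b − Φ_a) / ‖X_b − X_a‖     [SI/mm],

with the vector SIG being SIG·**n**. For a bright lumen, **n** points
inward and SIG is positive; up to a blood-viscosity factor it tracks the
wall shear stress pattern. Evaluation-style post-processing is included:
cross-section sampling at levels along a vessel axis (default 6 levels at
2.5 mm) and angular sites around each level (default 12 at 30°), Welch
t-tests between groups, and Pearson correlation against a reference map.

A synthetic phantom generator produces TOF-like tube volumes
(plateau-sigmoid or Gaussian radial profiles, optional azimuthal
modulation, seeded noise) with closed-form Φ and ∇Φ oracles, emulating a
pumped high-flow/low-flow tube experiment through an abstract `flow_scale`
that steepens the wall gradient.

## Worked example

Generate a noisy mid-flow phantom and run the full pipeline with automatic
threshold selection and cross-section sampling:

```python
from tofsig import PhantomSpec, generate_phantom, write_volume
from tofsig.pipeline import RunConfig, run_pipeline

vol, _ = generate_phantom(PhantomSpec(flow_scale=1.5, noise_sd=5.0, seed=42))
write_volume(vol, "phantom.nii.gz")

cfg = RunConfig(input="phantom.nii.gz", auto_iso=True, min_component_vertices=100,
                axis_point=(0, 0, -6.25), axis_direction=(0, 0, 1),
                out_csv="points.csv", out_table="sections.csv")
report = run_pipeline(cfg)
```

The run report contains (values printed by the code above):

```
iso_value   -0.6088            # suggested threshold, normalized SI scale
n_vertices  16843  components 1  flagged 339
sig mean+/-sd  0.468 0.306     # wall SIG, normalized SI per mm
sampling    {'n_rows': 72, 'missing_levels': []}
```

The iso value is the Otsu split lowered toward the smallest threshold that
keeps the vessel a single component; 16 843 wall isopoints survive noise
rejection in one connected component; 339 points were flagged (flat
gradient or inner point outside the grid) and excluded from summaries; the
mean wall SIG of 0.47 normalized-SI/mm summarizes the wall map; and the
6 × 12 cross-section design yields its full 72 rows. The same run is
available from the shell:

```sh
tofsig compute --input phantom.nii.gz --auto-iso --min-vertices 100 \
       --axis 0,0,-6.25:0,0,1 --out-csv points.csv --out-table sections.csv
```

`tofsig phantom`, `tofsig sample` and `tofsig stats` expose the generator,
the cross-section sampler and the group statistics individually.

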