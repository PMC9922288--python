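# cardioflow

Surface-based cardiac motion tracking and flow computation for time-resolved
(4D) left-heart imaging.

Given a labeled triangle mesh of the left-heart blood pool at end diastole
(left ventricle, left atrium, left atrial appendage, boundary rings at the
vessel cuts, and the LAA ostium ring) plus one target surface per cardiac
phase, `cardioflow`:

1. **Tracks** the surface through the cycle with an optimal-step nonrigid
   iterative-closest-point registration.  The cost combines four terms —
   a stiffness penalty `alpha * (M kron G)` on differences between
   neighbouring per-vertex affine transforms, a nearest-neighbour distance
   term `W (D X - U)`, a landmark term (`beta = 10`) that freezes the
   vessel-cut rings and prescribes the ostium motion, and a bi-directional
   term (`lambda = 0.5`) from subsampled target vertices back to the
   source.  The stiffness weight is lowered 100 → 1 in 100 steps for the
   chambers and 100 → 10 in 20 steps for the separately registered LAA;
   frames are chained forward (0 → 5 → … → 50 %RR) and backward
   (0 → 95 → … → 50 %RR) with the mid-cycle frame blended from both chains.
2. **Smooths** the vertex trajectories with least-squares cubic B-splines
   (15 interior knots), exportable at 0.5 ms resolution.
3. **Computes flow**: LV volume every 5 ms via the divergence theorem,
   transmitral flow as its time derivative, LAA-orifice flow by clipping the
   closed surface at a static ostium plane, and the scalar indices —
   E/A peak flow rates and times, peak time span, stroke volume, Ef/Af
   ratio, LAA peak outflow and the LAA surface-area change factor.

A built-in **synthetic phantom** (`cardioflow.synthetic_phantom`) generates
deforming LV + LA + LAA geometry with closed-form volume curves and flows,
so the whole pipeline is testable without any patient data.

## Command line

```sh
# generate a synthetic phantom dataset (meshes + analytic truth)
cardioflow phantom data/ --seed 1

# track it and compute flow curves + metrics
cardioflow all data/ results/ --fast --seed 1

# individual stages
cardioflow segment image.nii -o surface.ply --threshold 250
cardioflow track data/ tracked/ --fast
cardioflow flow tracked/ curves/
cardioflow metrics curves/ --frames-dir tracked/
```

`--fast` shortens the stiffness schedules to 25 (chambers) / 10 (LAA)
steps — the endpoints are unchanged — for CI-scale runs.  Outputs are
tracked per-frame meshes (PLY with region labels), volume and flow curves
(CSV, stamped with the run's config hash), and metrics as CSV + JSON.
Runs are deterministic: identical configs produce byte-identical CSVs.

Mesh I/O: ASCII STL, PLY and legacy VTK polydata (labels as a per-vertex
integer `region` attribute in PLY/VTK).  Images: NIfTI (`.nii`/`.nii.gz`)
and uncompressed MetaImage (`.mha`/`.mhd`).

## Library example

```python
from cardioflow import (PhantomSpec, generate_phantom_cycle, TrackingConfigs,
                        track_cycle, fit_motion_splines, volume_curve,
                        mitral_flow_curve, laa_flow_curve, laa_area_curve,
                        ostium_plane_from_labels, flow_metrics, Region)

data = generate_phantom_cycle(PhantomSpec())
seq = track_cycle(data.source, data.labels, data.targets_full,
                  data.targets_laa, configs=TrackingConfigs.fast(),
                  targets_chambers=data.targets_chambers)
motion = fit_motion_splines(seq)
lv = volume_curve(motion, seq.mesh, seq.labels, Region.LV)
mv = mitral_flow_curve(lv)
plane = ostium_plane_from_labels(seq.mesh, seq.labels)
laa = laa_flow_curve(motion, seq.mesh, seq.labels, plane)
metrics = flow_metrics(mv, laa, laa_area_curve(seq))
print(metrics.as_dict())
```
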