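# endofuse

Geometry toolkit for augmented-reality (AR) surgical navigation in
endoscopic skull-base surgery: it fuses structures segmented from an
intraoperative cone-beam CT (CBCT) onto the live endoscopic view, and
quantifies how accurately the overlay lands on the real anatomy.

The package is aimed at people building or evaluating image-guided
surgery systems: it contains the complete calibration and tracking
chain of such a system *and* a virtual rig that simulates every
physical component (phantoms, optical tracker, endoscope camera), so
the whole pipeline can be exercised, stress-tested and validated
without hardware.

## The model

Four coordinate frames are involved, written target←source:

* **O** — the optical tracking system (OTS) / world frame,
* **M** — the marker disc mounted on the endoscope, tracked by the OTS,
* **C** — the endoscope camera,
* **P** — the patient frame, defined by the CBCT volume.

With `T_XO` denoting the pose of frame X in the world (an O←X rigid
transform), the fusion chain is

```
T_CO = T_MO · T_CM                 (camera pose from the tracked marker)
T_CP = T_PO⁻¹ · (T_MO · T_CM)      (camera pose in the patient frame)
```

so a CBCT-frame point `x_P` appears in the image at `π(K, T_CP⁻¹ x_P)`,
where `π` is a distorted pinhole projection with intrinsics `K`.
The constituents are estimated by the classical methods:

* `K` — Zhang planar calibration from checkerboard views
  (closed-form from homographies + joint Levenberg–Marquardt refinement);
* `T_CO` — P3P (Grunert-style quartic) on a 25-marker calibration
  plate, disambiguated by surplus markers and refined by LM;
* `T_CM` — hand-eye calibration from paired (T_MO, T_CO) views, by
  per-sample averaging (both poses share the world frame) or by the
  classical AX = XB relative-motion formulation;
* `T_PO` — rigid point-set registration (SVD/Kabsch with reflection
  guard) of patient-surface markers against the virtual reference grid
  (VRG) frozen at CBCT time, which also compensates patient motion.

Overlay accuracy is measured with a grid phantom carrying 13 steel
spheres (Ø 2 mm) in the central 20×20 mm of a 60×60 mm plate and 11
tracking markers on its border.  The target registration error of each
sphere is the image distance between the real and the overlaid circle,
converted to millimetres with the known sphere diameter:

```
TRE[mm] = TRE[px] · Ø_sphere[mm] / Ø_sphere[px]
```

The evaluation protocol sweeps 6 working distances (5–30 mm) × ≥100
grid positions covering the field of view, and reports per-distance
statistics, one-way ANOVA with Tukey–Kramer post-hoc comparisons, and
spatial error heat maps.

## Worked example

```python
import numpy as np
from endofuse import run_accuracy_protocol, evaluate_run, summarize

run = run_accuracy_protocol(
    distances=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    positions_per_distance=100,
    sigma_marker_mm=0.05,   # optical-tracker noise per axis
    render=False,
    seed=1,
)
records = evaluate_run(run)
print(summarize(records, run.intrinsics.image_size).summary())
```

prints

```
TRE summary
  records : 6250
  mean±sd : 0.022 ± 0.011 mm
  median  : 0.021 mm (IQR 0.014–0.029)
  range   : 0.000 – 0.063 mm
  ANOVA across distances: F = 6.715, p = 0.000
```

i.e. with 0.05 mm tracker noise the simulated overlay is accurate to
about 0.02 mm on average, and at this noise level the small
distance-dependence of the error is statistically detectable.  With
`sigma_marker_mm=0` the same protocol yields a maximum TRE below
1e-12 mm — the pipeline is numerically exact when its inputs are — so
any error measured on real hardware is attributable to the sensors and
calibrations, not to the fusion algebra.

The same workflow is available from the shell:

```bash
endofuse --seed 1 --out-dir out run-accuracy --positions 100
endofuse --out-dir out report --records-csv out/tre_records.csv
```

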