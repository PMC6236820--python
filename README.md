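# lungmargin

Contour-based prediction of ipsilateral lung dose–volume metrics for breast
and chest-wall proton therapy.

## The problem

Before a proton plan exists, clinicians often need a realistic estimate of how
much ipsilateral lung (IL) will be irradiated — to set planning goals, to judge
the feasible benefit of protons, or to catch suboptimal plans. Highly conformal
proton plans have a useful geometric property: the falloff isodose surfaces
closely resemble uniform expansions of the planning target volume (PTV). That
makes the lung dose predictable from *contours alone*.

## The model

Expand the PTV isotropically by a margin *m* (mm) and measure the fraction of
the ipsilateral lung inside the expansion,

&nbsp;&nbsp;&nbsp;&nbsp;*V*(*m*) = |(PTV + *m*) ∩ IL| / |IL|.

*V*(*m*) is used as a predictor of the planned dose–volume metric
*V<sub>D</sub>* (fraction of lung receiving ≥ *D* Gy(RBE)). The margin is
calibrated per dose level over a cohort of already-planned cases, with every
plan rescaled to a 50.4 Gy(RBE) prescription:

&nbsp;&nbsp;&nbsp;&nbsp;*m<sub>D</sub>* = argmin<sub>*m*</sub> √⟨(*V*(*m*) − *V<sub>D</sub>*)²⟩ ,

where ⟨·⟩ averages over patients (RMSE, in percentage points of lung volume).
The mean error ME = ⟨*V*(*m*) − *V<sub>D</sub>*⟩ is tracked as a measure of
systematic bias, and cases are added to the cohort until the RMSE stops
changing (cohort-growth convergence). The shipped default model maps
**20 Gy(RBE) → 11 mm** and **5 Gy(RBE) → 22 mm**. Negative margins (shrinking
the PTV) are supported throughout.

The model fails in a known, directional way when conformality is deliberately
compromised (e.g. a medial cold spot to spare the heart): the prediction stays
put while the real lung dose drops, so the model *overestimates*. The package
reproduces this failure mode with a cold-spot phantom variant.

## What is in the package

- `lungmargin.geometry` / `lungmargin.morphology` — voxel grids, binary
  masks, exact anisotropic signed Euclidean distance maps, isotropic margin
  expansion/erosion (distance-map thresholding, so nesting is exact), overlap
  fractions and *V*(*m*) curves.
- `lungmargin.dvh` — prescription rescaling to the 50.4 Gy(RBE) reference,
  trilinear dose resampling onto structure grids, *V<sub>D</sub>* /
  *D<sub>V</sub>* queries on the empirical DVH, and the margin-indexed
  80%–20% falloff width.
- `lungmargin.model` — RMSE margin calibration, mean-error tracking,
  cohort-growth convergence, contour-only prediction, the shipped default
  model.
- `lungmargin.phantom` — synthetic thoracic phantoms (ellipsoidal lung,
  curved shell PTV abutting it across a chest-wall gap) with *exactly*
  conformal dose — isodose surfaces are PTV expansions by construction — plus
  jittered cohorts and the cold-spot variant.
- `lungmargin.io` — NIfTI masks/doses, DICOM RT-STRUCT rasterization
  (voxel-center-in-polygon, even-odd holes), DICOM RT-DOSE read/write, YAML
  cohort manifests.
- `lungmargin` CLI — `predict`, `calibrate`, `curve`, `phantom` subcommands.

## Worked example

```python
from lungmargin import DefaultModel, PhantomSpec, make_phantom, predict_volume

phantom = make_phantom(PhantomSpec(jitter_mm=0.0))   # synthetic thoracic case
model = DefaultModel.shipped()                        # 20->11 mm, 5->22 mm
for level in (20.0, 5.0):
    v = predict_volume(phantom.ptv, phantom.lung, model, level)
    print(f"predicted V_{level:g}Gy(RBE) = {100 * v:5.1f}%")
```

prints

```
predicted V_20Gy(RBE) =   8.1%
predicted V_5Gy(RBE) =  24.4%
```

— the fraction of the ipsilateral lung expected to receive at least 20 and
5 Gy(RBE) under a conformal 50.4 Gy(RBE) plan, computed from contours only.
On this phantom the planned (dose-computed) V₂₀ is also 8.07%, because the
phantom's dose is conformal by construction. The scripts in `examples/` walk
through prediction, calibration, the *V*(*m*)/DVH diagnostic and the
cold-spot failure mode.

Equivalent shell workflow:

```sh
lungmargin phantom --n 10 --seed 1 --out-dir cohort/
lungmargin calibrate --manifest cohort/manifest.yaml --dose-level 20 --out-dir fit/
lungmargin predict --manifest cohort/manifest.yaml --out-dir pred/
```

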