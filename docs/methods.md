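# Methods

## Model and assumptions

The package predicts an organ-at-risk dose–volume metric from contours alone.
For a dose level *D* (Gy(RBE), in a frame where the prescription is
50.4 Gy(RBE)), the predictor is the overlap fraction V(m) of the ipsilateral
lung with the PTV expanded isotropically by a margin m. The underlying
physical assumption is **dose conformality**: the falloff isodose surfaces of
a proton plan approximately coincide with uniform geometric expansions of the
target, so a single distance m summarises the average dose gradient around
the whole PTV surface. Everything patient-specific — lung size and shape,
target size and curvature, rib-cage thickness — enters implicitly through the
contours.

Calibration picks, per dose level, the margin minimising the root-mean-square
error of V(m) − V_D over a cohort of planned cases; the mean error (ME) is
reported alongside as a bias measure, and RMSE ≥ |ME| always. Errors are in
percentage points of lung volume. Dose levels are tied to the reference
prescription: each plan's dose is multiplied by 50.4/prescription before V_D
is read off, so one margin per dose level serves all prescriptions.

Key consequences of the assumption, both exercised by the tests: the model is
exact on perfectly conformal dose (parameter recovery), and it *overestimates*
when conformality is deliberately broken near the organ (cold spot) — the
prediction cannot drop because the contours did not change.

## Geometric conventions

- Voxel (i, j, k) has its center at `origin + (i,j,k)·spacing`, 0-based,
  patient-space mm, array axes = (x, y, z). A voxel belongs to a structure
  iff its center does.
- Signed distance = Euclidean distance to the nearest voxel **center** of the
  opposite class (exact anisotropic EDT; `scipy.ndimage.distance_transform_edt`),
  negative inside. This is the convention the exhaustive all-pairs test
  oracle checks to 1e-9 mm.
- Expansion by m thresholds the signed distance map of the *original* mask at
  m (`≤ m`, ties included), never iterated dilation: nesting is exact, m = 0
  is the bit-exact identity, negative m erodes. A positive expansion that
  reaches the grid boundary raises an error rather than clipping silently;
  `pad_mask` enlarges the frame by `ceil(m/spacing)+1` voxels per side.
- V_D counts voxels with `dose ≥ D` (closed threshold, matching the `≤` of
  expansion so conformal phantoms are self-consistent voxel by voxel). D_V is
  read off the empirical step DVH (the `ceil(V·n)`-th largest organ dose);
  linear interpolation is available but not the default, and the
  step convention is what makes the round-trip identity
  `dose_at_volume(volume_at_dose(D)) = D` hold exactly on achieved steps.
- Dose is always resampled onto the structure grid (trilinear, 0 outside the
  dose field), because structure grids define the voxel-counting frame.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| reference prescription | 50.4 Gy(RBE) | frame all plans are rescaled to |
| margin search grid | −10 … 40 mm, 0.5 mm steps | calibration candidates; RMSE ties break toward the smallest m (conservative prediction) |
| convergence window / tol / floor | 3 cases / 0.25 pp / n ≥ 10 | "RMSE stopped changing": largest change vs the previous `window` cohort sizes ≤ tol, never before 10 cases |
| falloff scan step δ | 1 mm | shell width for the 80%–20% falloff metric |
| default margins | 20 Gy(RBE) → 11 mm, 5 Gy(RBE) → 22 mm | shipped model (versioned JSON asset) |

The search granularity, tie rule and the operational convergence rule are
package design choices — mm-level reporting of calibrated margins suggests
roughly this resolution, but nothing finer is implied — and all three
convergence knobs are exposed as function arguments.

## The synthetic phantom

`PhantomSpec` describes one case: an ellipsoidal lung (default semi-axes
40 × 55 × 70 mm ≈ 0.65 L, a realistic adult single-lung volume), a PTV that is
a curved shell following the lung surface over an anterior cone (half-angle
55°) at a 5 mm chest-wall gap with 20 mm thickness (≈ 260 cc, a breast/
chest-wall-like target), on a 2 mm isotropic grid. The dose is constructed as
`prescription · f(max(0, d))` where d is the signed distance to the PTV and f
a piecewise-linear falloff anchored at (0 mm, 100%), (11 mm, 20/50.4),
(22 mm, 5/50.4), (35 mm, 0): the D isodose surface **is**
`expand(ptv, f⁻¹(D/Rx))`, voxel-exactly, because dose and expansion derive
from the same distance map under the same tie rules. Calibration on such a
cohort is therefore a parameter-recovery problem whose answer (11 mm, 22 mm)
is known by construction.

Cohorts jitter every mm-valued parameter per case — lung semi-axes, gap,
shell thickness, *and the falloff anchor distances* — with independent
Gaussian perturbations (scale `jitter_mm`, default 2 mm, truncated at ±2σ and
clipped to keep specs valid). The anchor jitter is what gives a jittered
cohort genuinely nonzero prediction error: geometry jitter alone would not,
since each case's dose is built from its own contours. Prescriptions cycle
through 50.4/45/63 Gy(RBE) so the reference rescaling is always exercised.
Everything is driven by one `numpy` generator seeded from `spec.seed`;
outputs are bit-reproducible.

What the phantom does **not** emulate: CT density (no water-equivalent path
lengths), heart/esophagus anatomy, breathing motion, beam-specific penumbra
differences, interior dose heterogeneity (the PTV is flat at prescription),
or realistic contour noise. Passing the phantom tests therefore shows the
*machinery* is correct (geometry, DVH accounting, optimisation, convergence
logic) and that the model is exact under its own conformality assumption; it
does not validate the 11/22 mm constants against clinical data, which is
inherently a planning-system exercise.

The cold-spot variant caps the dose at a floor inside a ball centered on the
PTV's medial-most point (`min(dose, floor)`), leaving the prediction
untouched; with a floor below 20 Gy(RBE) the planned V₂₀ strictly drops, and
the directional property (predicted ≥ actual) is asserted for both dose
levels. Note that capping *at exactly* a queried level D does not change V_D
under the closed `≥ D` threshold; demonstrations of a strict drop therefore
use a floor below the level queried.

## Numerical choices and degenerate inputs

- Distance maps require a mask that is neither empty nor grid-filling (no
  surface otherwise); overlap fractions require a nonempty organ; grid
  mismatches are errors, never implicit resampling.
- `dose_at_volume` rejects V = 0 (the supremum is unbounded); V = 1 returns
  the minimum organ dose. A 1e-12 slack in `ceil(V·n)` absorbs float division
  round-off.
- The falloff width scans 1 mm shells out to 80 mm and reports
  m(lo) − m(hi) of the first shell-mean crossings; if the dose never falls
  below the low level it raises rather than extrapolating.
- RT-STRUCT rasterization is voxel-center-in-polygon with the even-odd rule
  (nested contours toggle, producing rings); contours land on the nearest
  slice; only planar contours and axis-aligned geometry are supported.
  RT-DOSE writing quantises to uint32 with a max-derived scaling (round trip
  lossless to ≈ max/2³²).

## Problem sizes

The default phantom grid is ~2.1 M voxels (2 mm isotropic); a 10-case
noiseless calibration cohort plus both calibrations runs in well under a
minute on one CPU, and the margin sweep is amortised by caching each case's
lung-restricted PTV distances. The unit-test fixtures use a reduced geometry
(lung semi-axes 20 × 26 × 32 mm) with identical conventions. The acceptance
script uses the full default geometry: n = 10 noiseless for calibration and
n = 14 jittered for the convergence procedure.

## Known limitations

- Geometric margins only: no water-equivalent (density-weighted) expansion,
  so the CT-density limitation of the underlying model is inherited.
- One margin per dose level; no joint fit of the whole falloff curve.
- Axis-aligned DICOM/NIfTI geometry only; no oblique orientations, RT-PLAN,
  boost summation, or clinical structure-name heuristics beyond a small
  configurable pattern map.
- The convergence rule is an operationalisation of "RMSE stopped changing";
  stream order is caller-controlled and matters for the reported n.
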