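"""When the model fails: compromised conformality (a medial cold spot).

The contour-only model assumes the dose falls off uniformly around the PTV.
If part of the target is deliberately underdosed (e.g. to spare the heart),
the real lung dose drops but the contour prediction cannot know that: the
model then overestimates.  This script reproduces that direction of error.
"""

from lungmargin import (
    DefaultModel,
    FalloffProfile,
    PhantomSpec,
    cold_spot_variant,
    conformal_dose,
    make_phantom,
    medial_cold_spot_region,
    predict_volume,
    volume_at_dose,
)

spec = PhantomSpec(jitter_mm=0.0)
phantom = make_phantom(spec)
dose = conformal_dose(phantom.ptv, FalloffProfile(), spec.prescription)

region = medial_cold_spot_region(phantom.ptv, radius_mm=30.0)
compromised = cold_spot_variant(dose, phantom.ptv, region, floor=18.0)

model = DefaultModel.shipped()
predicted = 100 * predict_volume(phantom.ptv, phantom.lung, model, 20.0)
actual = 100 * volume_at_dose(compromised, phantom.lung, 20.0)
conformal = 100 * volume_at_dose(dose, phantom.lung, 20.0)

print(f"conformal plan     V_20 = {conformal:5.2f}%")
print(f"cold-spot plan     V_20 = {actual:5.2f}%")
print(f"contour prediction V_20 = {predicted:5.2f}%")
print(f"-> model overestimates by {predicted - actual:.2f} pp "
      "(prediction is unchanged; the plan got colder)")
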