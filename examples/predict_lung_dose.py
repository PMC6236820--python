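"""Contour-only prediction of ipsilateral lung V_20 and V_5.

Builds one synthetic thoracic case (lung + breast-like PTV) and predicts the
lung dose-volume metrics from the contours alone, using the shipped margins
(11 mm for 20 Gy(RBE), 22 mm for 5 Gy(RBE)).  No dose grid is involved: this
is the estimate available before any treatment plan exists.
"""

from lungmargin import DefaultModel, PhantomSpec, make_phantom, predict_volume

spec = PhantomSpec(jitter_mm=0.0)
phantom = make_phantom(spec)
model = DefaultModel.shipped()

print(f"PTV volume:  {phantom.ptv.volume_cc:7.1f} cc")
print(f"lung volume: {phantom.lung.volume_cc:7.1f} cc")
for level in (20.0, 5.0):
    margin = model.margin_for(level)
    v = predict_volume(phantom.ptv, phantom.lung, model, level)
    print(f"predicted V_{level:g}Gy(RBE) = {100 * v:5.1f}%   (PTV + {margin:g} mm)")

# The percentages are the fraction of the ipsilateral lung expected to receive
# at least 20 / 5 Gy(RBE) under a conformal 50.4 Gy(RBE) plan.
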