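"""Measure the stained-area fraction of an ROI and compare with truth.

Detection happens on inverted intensity: a pixel is stained when it
exceeds the ROI's robust background (median) by k = 5 scaled MADs.
"""

from ps6quant import StainFieldSpec, generate_section, measure_roi
from ps6quant.quantify import RegionROI, estimate_background

spec = StainFieldSpec(seed=7)
image, truth = generate_section(spec)
h, w = image.shape
roi = RegionROI(region="NDI",
                polygon=[(5.5, 5.5), (w - 6.5, 5.5), (w - 6.5, h - 6.5),
                         (5.5, h - 6.5)])

bg = estimate_background(image, roi)
m = measure_roi(image, roi, k=5.0)
true = truth.fraction(roi.pixel_mask(image.shape))

print(f"background (inverted): {bg.level:.3f} +/- {bg.mad:.3f} MAD")
print(f"threshold used:        {m.threshold_used:.3f}")
print(f"measured fraction:     {m.fraction:.4f}  "
      f"({m.stained_area_um2:.0f} of {m.total_area_um2:.0f} um^2)")
print(f"true fraction:         {true:.4f}")
# measured and true fractions agree to ~1e-3 at the default noise level
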