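"""Predict the post-placement IVC diameter from one pair of measurements.

The vessel cross-section is oval before filter placement and near-circular
after, so neither the maximum nor the minimum projected diameter alone is a
good predictor of the final size.  The circle-fitting model approximates the
oval's circumference (Ramanujan) and converts it to the diameter of the
circle with the same circumference.
"""

from ivcfit import VesselDiameters, predict_equivalent_diameter

# published patient-cohort mean diameters (mm) as a worked example
pre = VesselDiameters(d_max=22.07, d_min=15.95, stage="pre")
result = predict_equivalent_diameter(pre)

print(f"pre-placement:  D_max = {pre.d_max:.2f} mm, D_min = {pre.d_min:.2f} mm")
print(f"ellipse axes:   a = {result.axes.a:.3f} mm, b = {result.axes.b:.3f} mm")
print(f"circumference:  C = {result.circumference:.2f} mm  (Ramanujan approximation)")
print(f"equivalent diameter: D_eq = {result.d_eq:.2f} mm")
print()
print(
    "D_eq is the predicted post-placement diameter: it always lies between\n"
    "D_min and D_max, closer to whichever the oval is closer to a circle."
)
for filter_mm in (25.0, 28.0, 32.0):
    print(f"candidate filter {filter_mm:.0f} mm -> oversizing ratio {filter_mm / result.d_eq:.2f}")
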