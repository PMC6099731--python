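"""Fit the two assay calibration lines and back-calculate a dialysate sample.

The drug (GE) assay is linear over 5-4000 ng/mL and the biomarker (PGE2)
assay over 100-10,000 pg/mL; both report analyte/internal-standard peak-area
ratios.  Samples outside the standards are flagged, not rejected.
"""

from micropkpd import back_calculate, fit_calibration

# standards lying exactly on each validated regression line
ge = fit_calibration(
    [(c, 0.00246 * c + 1.84e-4) for c in (5, 50, 250, 1000, 4000)], analyte="GE"
)
pge2 = fit_calibration(
    [(c, 2.74e-5 * c - 0.00382) for c in (100, 500, 2500, 10000)], analyte="PGE2"
)

for curve in (ge, pge2):
    print(
        f"{curve.analyte}: response = {curve.slope:.3g} x conc + {curve.intercept:.3g}"
        f"  (r = {curve.correlation:.5f}, valid = {curve.is_valid})"
    )

sample = back_calculate(ge, response=0.2958)
print(f"sample at response 0.2958 -> {sample.value:.1f} ng/mL, in range: {sample.in_range}")
peaky = back_calculate(ge, response=ge.response_at(5200.0))
print(f"a peak sample back-calculates to {peaky.value:.0f} ng/mL, in range: {peaky.in_range}")
print("(the flag marks extrapolation beyond the highest standard, common near Tmax)")
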