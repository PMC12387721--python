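"""Measure TTF and CNR on a synthetic ACR-style multi-pin phantom.

Renders a 200 mm phantom (bone / polyethylene / air / acrylic pins) with a
0.5 mm Gaussian reconstruction blur and 5 HU noise, runs the two-stage
pipeline, and prints one row per pin.
"""

import cttf

spec = cttf.preset("acr_like", seed=1)
img, truth = cttf.render(spec)
meas = cttf.measure_slice(img, "computational_acr")

print(f"body diameter: {meas.body_diameter_mm:.1f} mm "
      f"(ROI diameter = {meas.body_diameter_mm / 10:.1f} mm)")
print(f"{'material':14s} {'CNR':>8s} {'f50 (1/mm)':>11s} {'f10 (1/mm)':>11s}")
for res in meas.results:
    print(f"{res.material_name:14s} {res.cnr:8.1f} {res.f50_inv_mm:11.3f} {res.f10_inv_mm:11.3f}")

print(f"\nkernel ground truth: f50 = {truth.pins[0]['f50_inv_mm']:.3f} 1/mm")
print("Every pin reports the same f50 regardless of its contrast (the blur is")
print("shift-invariant here), and each measured f50 should sit within a few")
print("percent of the kernel's closed-form value above; CNR is contrast/noise.")
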