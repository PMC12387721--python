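"""Why TTF instead of MTF: contrast-dependent resolution.

Iterative and deep-learning CT reconstructions sharpen high-contrast edges
more than low-contrast ones, so a single MTF misrepresents the system.  The
generator emulates this with a per-pin blur map; the measured per-material
TTF then separates where a single MTF could not.
"""

import cttf

blur = {
    "body": cttf.GaussianBlur(0.5),
    "Bone": cttf.GaussianBlur(0.35),       # high contrast: reconstructed sharper
    "Air": cttf.GaussianBlur(0.40),
    "Polyethylene": cttf.GaussianBlur(0.55),
    "Acrylic": cttf.GaussianBlur(0.60),    # low contrast: reconstructed softer
}
spec = cttf.preset("acr_like", seed=3, blur=blur)
img, truth = cttf.render(spec)
meas = cttf.measure_slice(img, "computational_acr")

print(f"{'material':14s} {'CNR':>7s} {'f50 meas':>9s} {'f50 true':>9s}")
for res in meas.results:
    gt = truth.pin(res.material_name)
    print(f"{res.material_name:14s} {res.cnr:7.1f} {res.f50_inv_mm:9.3f} {gt['f50_inv_mm']:9.3f}")
print("\nBone resolves finer detail (larger f50) than acrylic on the same")
print("image — exactly the contrast dependence the TTF is designed to expose.")
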