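"""Body segmentation, masking, pin localization and ROI statistics."""

import numpy as np
import pytest

import cttf
from cttf.image_io import HUImage
from cttf.segmentation import (
    PinNotFoundError,
    SegmentationError,
    apply_body_mask,
    place_rois,
    segment_body,
    segment_pins,
)


def _disk_image(diameter_mm, spacing=0.5, fov_mm=None, body_hu=0.0, air_hu=-1000.0):
    fov_mm = fov_mm or diameter_mm * 1.3
    n = int(round(fov_mm / spacing))
    c = fov_mm / 2
    yy, xx = np.meshgrid((np.arange(n) + 0.5) * spacing, (np.arange(n) + 0.5) * spacing, indexing="ij")
    img = np.where((yy - c) ** 2 + (xx - c) ** 2 <= (diameter_mm / 2) ** 2, body_hu, air_hu)
    return HUImage(pixels=img, spacing_mm=(spacing, spacing))


@pytest.mark.parametrize("diameter", [100.0, 150.0, 200.0, 250.0])
def test_body_diameter_within_one_pixel(diameter):
    img = _disk_image(diameter)
    body = segment_body(img)
    assert abs(body.diameter_mm - diameter) <= img.spacing_mm[0]
    assert abs(body.center_mm[0] - img.extent_mm()[0] / 2) <= img.spacing_mm[0]


def test_disconnected_speck_excluded():
    img = _disk_image(200.0)
    img.pixels[2:4, 2:4] = 100.0  # 4-px speck in the air corner
    body = segment_body(img)
    assert not body.mask[2, 2]
    assert abs(body.diameter_mm - 200.0) <= img.spacing_mm[0]


def test_air_pin_hole_filled_and_area_preserved():
    img = _disk_image(200.0)
    c = img.extent_mm()[0] / 2
    yy, xx = img.coords_mm()
    img.pixels[(yy - c + 50) ** 2 + (xx - c) ** 2 <= 12.5**2] = -1000.0  # air pin
    body = segment_body(img)
    true_area = np.pi * 100.0**2
    seg_area = body.mask.sum() * img.spacing_mm[0] * img.spacing_mm[1]
    assert abs(seg_area - true_area) / true_area < 0.01


def test_no_foreground_is_segmentation_error():
    img = HUImage(pixels=np.full((32, 32), -1000.0), spacing_mm=(0.5, 0.5))
    with pytest.raises(SegmentationError):
        segment_body(img)


def test_mask_zeroes_exterior_exactly_and_keeps_interior():
    img = _disk_image(200.0, body_hu=120.0)
    body = segment_body(img)
    masked = apply_body_mask(img, body)
    assert (masked.pixels[~body.mask] == 0.0).all()
    np.testing.assert_array_equal(masked.pixels[body.mask], img.pixels[body.mask])


def test_all_foreground_mask_is_identity():
    img = _disk_image(200.0, body_hu=50.0)
    body = segment_body(img)
    body.mask[:] = True
    np.testing.assert_array_equal(apply_body_mask(img, body).pixels, img.pixels)


def test_mask_shape_mismatch_rejected():
    img = _disk_image(100.0)
    body = segment_body(img)
    small = HUImage(pixels=np.zeros((10, 10)), spacing_mm=(0.5, 0.5))
    with pytest.raises(ValueError):
        apply_body_mask(small, body)


def _pins_for(img, template_name):
    template = cttf.get_template(template_name)
    body = segment_body(img, template.body_threshold_hu)
    masked = apply_body_mask(img, body)
    return segment_pins(masked, body, template), body, masked


@pytest.mark.parametrize(
    "fixture_name,template",
    [
        ("acr_rendered", "computational_acr"),
        ("aapm_rendered", "aapm"),
        ("catphan_rendered", "catphan604"),
    ],
)
def test_all_pins_localized_within_one_pixel(fixture_name, template, request):
    img, truth = request.getfixturevalue(fixture_name)
    pins, _, _ = _pins_for(img, template)
    assert len(pins) == cttf.get_template(template).expected_pin_count
    for p in pins:
        gt = truth.pin(p.material_name)
        err = np.hypot(p.centroid_mm[0] - gt["center_mm"][0], p.centroid_mm[1] - gt["center_mm"][1])
        assert err <= img.spacing_mm[0], f"{p.material_name}: {err:.2f} mm off"


@pytest.mark.parametrize("spacing", [0.3125, 0.5, 1.0])
def test_localization_across_pixel_spacings(spacing):
    grid = int(round(200.0 / spacing))
    spec = cttf.preset("acr_like", seed=3, grid_px=grid)
    img, truth = cttf.render(spec)
    pins, _, _ = _pins_for(img, "computational_acr")
    for p in pins:
        gt = truth.pin(p.material_name)
        err = np.hypot(p.centroid_mm[0] - gt["center_mm"][0], p.centroid_mm[1] - gt["center_mm"][1])
        assert err <= spacing


def test_missing_pin_error_names_material():
    spec = cttf.preset("acr_like", seed=4)
    spec.pins = [p for p in spec.pins if p.material != "Acrylic"]
    img, _ = cttf.render(spec)
    with pytest.raises(PinNotFoundError, match="Acrylic"):
        _pins_for(img, "computational_acr")


def test_roi_diameter_is_tenth_of_body(acr_measurement):
    for roi in acr_measurement.rois:
        assert roi.roi_diameter_mm == pytest.approx(acr_measurement.body_diameter_mm / 10)


def test_noiseless_pins_have_exact_means_and_flagged_cnr(sharp_noiseless_acr):
    img, truth = sharp_noiseless_acr
    pins, body, masked = _pins_for(img, "computational_acr")
    rois = place_rois(masked, body, pins)
    by_name = {r.material_name: r for r in rois}
    assert by_name["Bone"].inner_mean_hu == pytest.approx(955.0)
    assert by_name["Bone"].outer_mean_hu == pytest.approx(0.0)
    assert np.isinf(by_name["Bone"].cnr)
    assert "zero-noise" in by_name["Bone"].flags


def test_cnr_matches_analytic_value(acr_measurement):
    # bone pin: |955 - 0| / 5 HU ≈ 191, within Monte-Carlo sampling error
    bone = next(r for r in acr_measurement.rois if r.material_name == "Bone")
    assert bone.cnr == pytest.approx(955.0 / 5.0, rel=0.05)


def test_cnr_invariant_to_constant_offset(acr_rendered):
    img, _ = acr_rendered
    pins, body, masked = _pins_for(img, "computational_acr")
    rois0 = place_rois(masked, body, pins)
    shifted = HUImage(pixels=masked.pixels + 37.0 * body.mask, spacing_mm=img.spacing_mm)
    rois1 = place_rois(shifted, body, pins)
    for a, b in zip(rois0, rois1):
        assert b.cnr == pytest.approx(a.cnr, rel=1e-9)


def test_doubling_noise_halves_cnr():
    cnrs = {}
    for sd in (5.0, 10.0):
        vals = []
        for seed in range(3):
            spec = cttf.preset("acr_like", seed=seed, noise_sd_hu=sd)
            img, _ = cttf.render(spec)
            pins, body, masked = _pins_for(img, "computational_acr")
            rois = place_rois(masked, body, pins)
            vals.append(next(r.cnr for r in rois if r.material_name == "Bone"))
        cnrs[sd] = np.mean(vals)
    assert cnrs[5.0] / cnrs[10.0] == pytest.approx(2.0, rel=0.1)
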