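"""Stage 1: phantom body segmentation, pin detection and ROI placement.

The phantom body is isolated by thresholding at −200 HU (water-equivalent
body vs. surrounding air), keeping the largest connected component and
filling holes.  Its equivalent-circle diameter sets the measurement ROI
size: each pin gets an inner disk ROI of diameter 1/10 of the phantom
diameter, plus a concentric background annulus just outside the pin edge
from which the background mean and noise (and hence CNR) are taken.

Pins are found per material by HU-window thresholding of the masked image,
restricted to an interior search region (< 0.8× body radius, so the phantom
shell cannot masquerade as a high-density pin), with connected components
accepted only when their area is within [25%, 400%] of the template's
nominal pin area.  Materials whose windows overlap (the AAPM phantom's
acrylic / polycarbonate / nylon) are disambiguated by the template's
expected polar angles via optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .image_io import HUImage
from .phantom_model import PhantomTemplate

__all__ = [
    "BodyMask",
    "PinDetection",
    "PinROI",
    "SegmentationError",
    "PinNotFoundError",
    "AmbiguityError",
    "InsufficientBackgroundError",
    "segment_body",
    "apply_body_mask",
    "segment_pins",
    "place_rois",
]


class SegmentationError(RuntimeError):
    """Body or pin segmentation failed."""


class PinNotFoundError(SegmentationError):
    def __init__(self, material: str, detail: str = ""):
        self.material = material
        msg = f"pin not found for material {material!r}"
        super().__init__(msg + (f": {detail}" if detail else ""))


class AmbiguityError(SegmentationError):
    """Two materials resolved to the same pin component."""


class InsufficientBackgroundError(SegmentationError):
    """Fewer than the minimum background pixels remain after clipping."""


@dataclass
class BodyMask:
    """Binary phantom-body mask with equivalent-circle diameter."""

    mask: np.ndarray  # bool, aligned to the source HUImage
    diameter_mm: float
    center_mm: tuple[float, float]  # (row_mm, col_mm)
    spacing_mm: tuple[float, float]

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class PinDetection:
    """One detected pin: material, binary-mask centroid, equivalent radius."""

    material_name: str
    centroid_mm: tuple[float, float]  # (row_mm, col_mm)
    radius_mm: float
    area_px: int = 0


@dataclass
class PinROI:
    """Measurement geometry and first-order statistics for one pin.

    ``cnr`` is |inner mean − background mean| / background standard
    deviation.  With a noiseless background the ratio diverges; it is then
    reported as ``inf`` with a ``zero-noise`` flag rather than an error, so
    noiseless synthetic inputs remain measurable.
    """

    material_name: str
    centroid_mm: tuple[float, float]
    roi_diameter_mm: float
    pin_radius_mm: float
    inner_mean_hu: float
    outer_mean_hu: float
    outer_sd_hu: float
    cnr: float
    inner_mask: np.ndarray = field(repr=False)
    outer_mask: np.ndarray = field(repr=False)
    flags: list[str] = field(default_factory=list)


def _pixel_center_grids(img: HUImage) -> tuple[np.ndarray, np.ndarray]:
    return img.coords_mm()


def segment_body(img: HUImage, threshold_hu: float = -200.0) -> BodyMask:
    """Isolate the phantom body as the largest connected component above
    ``threshold_hu``, fill internal holes (air pins belong to the body), and
    measure the equivalent-circle diameter from the filled area.
    """
    fg = img.pixels > threshold_hu
    if not fg.any():
        raise SegmentationError(f"no pixels above body threshold {threshold_hu} HU")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    body = labels == counts.argmax()
    body = ndimage.binary_fill_holes(body)

    touches = (
        body[0, :].any() and body[-1, :].any() and body[:, 0].any() and body[:, -1].any()
    )
    if touches:
        warnings.warn(
            "phantom body touches all four image borders; field of view may crop it",
            stacklevel=2,
        )
    sr, sc = img.spacing_mm
    area_mm2 = body.sum() * sr * sc
    diameter_mm = 2.0 * np.sqrt(area_mm2 / np.pi)
    rows, cols = np.nonzero(body)
    center = (
        img.origin_mm[0] + (rows.mean() + 0.5) * sr,
        img.origin_mm[1] + (cols.mean() + 0.5) * sc,
    )
    if body.mean() < 0.05:
        warnings.warn("phantom occupies < 5% of the image; check input", stacklevel=2)
    return BodyMask(mask=body, diameter_mm=float(diameter_mm), center_mm=center, spacing_mm=(sr, sc))


def apply_body_mask(img: HUImage, body: BodyMask) -> HUImage:
    """Zero everything outside the body mask (air → exactly 0 HU)."""
    if body.mask.shape != img.pixels.shape:
        raise ValueError(
            f"mask shape {body.mask.shape} does not match image {img.pixels.shape}"
        )
    out = np.where(body.mask, img.pixels, 0.0)
    return HUImage(pixels=out, spacing_mm=img.spacing_mm, origin_mm=img.origin_mm, meta=dict(img.meta))


def _pin_candidates(
    masked: HUImage,
    search: np.ndarray,
    lo: float,
    hi: float,
    area_lo_px: float,
    area_hi_px: float,
) -> list[PinDetection]:
    binmask = (masked.pixels >= lo) & (masked.pixels <= hi) & search
    labels = measure.label(binmask, connectivity=2)  # 8-connectivity
    out: list[PinDetection] = []
    sr, sc = masked.spacing_mm
    for region in measure.regionprops(labels):
        if not (area_lo_px <= region.area <= area_hi_px):
            continue
        r, c = region.centroid
        centroid = (
            masked.origin_mm[0] + (r + 0.5) * sr,
            masked.origin_mm[1] + (c + 0.5) * sc,
        )
        radius = float(np.sqrt(region.area * sr * sc / np.pi))
        out.append(PinDetection("", centroid, radius, area_px=int(region.area)))
    return out


def _angle_deg(center: tuple[float, float], point: tuple[float, float]) -> float:
    """Polar angle of ``point`` about ``center``, math convention (CCW, +y up).

    Image rows increase downward, so the row offset is negated.
    """
    drow = point[0] - center[0]
    dcol = point[1] - center[1]
    return float(np.degrees(np.arctan2(-drow, dcol)) % 360.0)


def _overlap_groups(template: PhantomTemplate) -> list[list[int]]:
    """Indices of windows grouped by HU-interval overlap (transitive)."""
    n = len(template.windows)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            wi, wj = template.windows[i], template.windows[j]
            if wi.lower_hu <= wj.upper_hu and wj.lower_hu <= wi.upper_hu:
                adj[i][j] = adj[j][i] = True
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, group = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            group.append(k)
            stack.extend(j for j in range(n) if adj[k][j])
        groups.append(sorted(group))
    return groups


def segment_pins(
    masked: HUImage, body: BodyMask, template: PhantomTemplate
) -> list[PinDetection]:
    """Locate one pin per template material on the masked image.

    Returns one :class:`PinDetection` per material, in template order.
    Raises :class:`PinNotFoundError` (naming the material) when a window has
    no acceptable component, and :class:`AmbiguityError` when two materials
    cannot be separated.
    """
    rows_mm, cols_mm = _pixel_center_grids(masked)
    dist = np.hypot(rows_mm - body.center_mm[0], cols_mm - body.center_mm[1])
    search = (dist < 0.8 * body.radius_mm) & body.mask

    sr, sc = masked.spacing_mm
    nominal_area_px = np.pi * template.nominal_pin_radius_mm**2 / (sr * sc)
    area_lo, area_hi = 0.25 * nominal_area_px, 4.0 * nominal_area_px

    per_material: dict[str, list[PinDetection]] = {}
    for w in template.windows:
        cands = _pin_candidates(masked, search, w.lower_hu, w.upper_hu, area_lo, area_hi)
        per_material[w.material_name] = cands

    def _same(a: PinDetection, b: PinDetection) -> bool:
        return (
            np.hypot(a.centroid_mm[0] - b.centroid_mm[0], a.centroid_mm[1] - b.centroid_mm[1])
            < template.nominal_pin_radius_mm
        )

    results: dict[str, PinDetection] = {}
    for group in _overlap_groups(template):
        materials = [template.windows[i].material_name for i in group]
        if len(group) == 1:
            m = materials[0]
            cands = per_material[m]
            if not cands:
                raise PinNotFoundError(m, "no component in HU window passed the area filter")
            best = max(cands, key=lambda p: p.area_px)
            results[m] = PinDetection(m, best.centroid_mm, best.radius_mm, best.area_px)
            continue

        # Overlapping windows: pool distinct candidates, assign by expected angle.
        pool: list[PinDetection] = []
        allowed: dict[str, list[int]] = {m: [] for m in materials}
        for m in materials:
            for cand in per_material[m]:
                idx = next((k for k, p in enumerate(pool) if _same(p, cand)), None)
                if idx is None:
                    pool.append(cand)
                    idx = len(pool) - 1
                allowed[m].append(idx)
        for m in materials:
            if not allowed[m]:
                raise PinNotFoundError(m, "no component in HU window passed the area filter")
        angles = {
            template.windows[i].material_name: template.windows[i].expected_angle_deg
            for i in group
        }
        if any(a is None for a in angles.values()):
            raise AmbiguityError(
                f"materials {materials} have overlapping HU windows but the template "
                "gives no expected angles to separate them"
            )
        big = 1e6
        cost = np.full((len(materials), len(pool)), big)
        for mi, m in enumerate(materials):
            for idx in allowed[m]:
                d = abs(_angle_deg(body.center_mm, pool[idx].centroid_mm) - angles[m])
                cost[mi, idx] = min(d, 360.0 - d)
        rows_i, cols_i = linear_sum_assignment(cost)
        for mi, ci in zip(rows_i, cols_i):
            if cost[mi, ci] >= big:
                raise AmbiguityError(
                    f"could not assign a distinct pin to material {materials[mi]!r}"
                )
            p = pool[ci]
            results[materials[mi]] = PinDetection(
                materials[mi], p.centroid_mm, p.radius_mm, p.area_px
            )

    ordered = [results[w.material_name] for w in template.windows]
    for p in ordered:
        r = int((p.centroid_mm[0] - masked.origin_mm[0]) / sr - 0.5)
        c = int((p.centroid_mm[1] - masked.origin_mm[1]) / sc - 0.5)
        if not body.mask[np.clip(r, 0, body.mask.shape[0] - 1), np.clip(c, 0, body.mask.shape[1] - 1)]:
            raise SegmentationError(f"{p.material_name}: centroid fell outside the body mask")
    return ordered


def place_rois(
    masked: HUImage,
    body: BodyMask,
    pins: list[PinDetection],
    min_background_px: int = 50,
    edge_guard_mm: float = 2.0,
) -> list[PinROI]:
    """Place inner disk + background annulus ROIs at each pin centroid.

    The inner ROI is a disk of diameter ``body.diameter_mm / 10`` centred at
    the pin centroid.  The background annulus spans 1.0–1.5 pin radii from
    the centroid, clipped to the body and away from every other pin; its
    inner boundary is additionally pushed out by ``edge_guard_mm`` so the
    blurred edge transition does not leak into the noise estimate (2 mm
    covers 4σ of a 0.5 mm reconstruction blur).
    """
    rows_mm, cols_mm = _pixel_center_grids(masked)
    roi_diameter = body.diameter_mm / 10.0
    roi_radius = roi_diameter / 2.0

    dists = [
        np.hypot(rows_mm - p.centroid_mm[0], cols_mm - p.centroid_mm[1]) for p in pins
    ]
    out: list[PinROI] = []
    for i, pin in enumerate(pins):
        d = dists[i]
        flags: list[str] = []
        inner = d <= roi_radius
        if roi_radius > pin.radius_mm:
            flags.append("roi-exceeds-pin")
        r_in = pin.radius_mm + edge_guard_mm
        r_out = max(1.5 * pin.radius_mm, r_in + edge_guard_mm)
        outer = (d > r_in) & (d <= r_out) & body.mask
        for j, other in enumerate(pins):
            if j != i:
                outer &= dists[j] > 1.6 * other.radius_mm
        n_bg = int(outer.sum())
        if n_bg < min_background_px:
            raise InsufficientBackgroundError(
                f"{pin.material_name}: only {n_bg} background pixels remain "
                f"(minimum {min_background_px})"
            )
        inner_mean = float(masked.pixels[inner].mean())
        outer_vals = masked.pixels[outer]
        outer_mean = float(outer_vals.mean())
        outer_sd = float(outer_vals.std())
        if outer_sd == 0.0:
            cnr = float("inf")
            flags.append("zero-noise")
        else:
            cnr = abs(inner_mean - outer_mean) / outer_sd
        out.append(
            PinROI(
                material_name=pin.material_name,
                centroid_mm=pin.centroid_mm,
                roi_diameter_mm=roi_diameter,
                pin_radius_mm=pin.radius_mm,
                inner_mean_hu=inner_mean,
                outer_mean_hu=outer_mean,
                outer_sd_hu=outer_sd,
                cnr=cnr,
                inner_mask=inner,
                outer_mask=outer,
                flags=flags,
            )
        )
    return out
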