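"""Synthetic multi-pin phantom renderer with exact ground truth.

Renders a circular water-equivalent body (surrounded by −1000 HU air) with
disk inserts at material-typical CT numbers, degraded by a blur kernel with
a closed-form TTF and by i.i.d. Gaussian noise.  Because geometry, kernel
and noise are all known, every pipeline stage can be checked against ground
truth: centroids, pin areas, CNR, and the kernel's analytic f50/f10.

Rendering strategy: the exact disk geometry is rasterized on an 8×
supersampled grid, the blur kernel is applied at that resolution, and the
final image samples the blurred field at the pixel centres (mean of the
central 2×2 subsamples, an aperture of 1/4 subpixel).  Sampling at points —
rather than averaging each full pixel — means no detector-aperture term is
folded in, so the blur kernel's closed-form TTF is exactly the TTF of the
rendered image below the Nyquist frequency.  Noise is added per final pixel
from a seeded generator, making images bit-reproducible.

Per-pin kernels are supported (each insert blurred with its own kernel, by
linearity) to emulate the contrast-dependent resolution of iterative and
deep-learning reconstructions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import HUImage
from .phantom_model import get_template

__all__ = [
    "BlurKernel",
    "NoBlur",
    "GaussianBlur",
    "LogisticBlur",
    "PinSpec",
    "PhantomSpec",
    "GroundTruth",
    "render",
    "preset",
    "preset_names",
]


class BlurKernel:
    """Isotropic blur with a closed-form TTF (radial OTF)."""

    def ttf(self, f_inv_mm: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def f50(self) -> float:
        raise NotImplementedError

    def f10(self) -> float:
        raise NotImplementedError

    def support_mm(self) -> float:
        """Half-width beyond which the PSF is negligible."""
        raise NotImplementedError

    def apply(self, arr: np.ndarray, spacing_mm: float) -> np.ndarray:
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class NoBlur(BlurKernel):
    def ttf(self, f_inv_mm):
        return np.ones_like(np.asarray(f_inv_mm, dtype=float))

    def f50(self) -> float:
        return float("inf")

    def f10(self) -> float:
        return float("inf")

    def support_mm(self) -> float:
        return 0.0

    def apply(self, arr, spacing_mm):
        return arr

    def describe(self) -> dict:
        return {"kind": "none"}


@dataclass(frozen=True)
class GaussianBlur(BlurKernel):
    """Gaussian PSF with standard deviation ``sigma_mm``.

    TTF(f) = exp(−2π²σ²f²); f50 = √(ln 2)/(√2 π σ), f10 = √(ln 10)/(√2 π σ).
    """

    sigma_mm: float

    def ttf(self, f_inv_mm):
        f = np.asarray(f_inv_mm, dtype=float)
        return np.exp(-2 * np.pi**2 * self.sigma_mm**2 * f**2)

    def f50(self) -> float:
        return math.sqrt(math.log(2)) / (math.sqrt(2) * math.pi * self.sigma_mm)

    def f10(self) -> float:
        return math.sqrt(math.log(10)) / (math.sqrt(2) * math.pi * self.sigma_mm)

    def support_mm(self) -> float:
        return 6.0 * self.sigma_mm

    def apply(self, arr, spacing_mm):
        return ndimage.gaussian_filter(arr, self.sigma_mm / spacing_mm, mode="nearest")

    def describe(self) -> dict:
        return {"kind": "gaussian", "sigma_mm": self.sigma_mm}


@dataclass(frozen=True)
class LogisticBlur(BlurKernel):
    """Isotropic PSF whose radial OTF is s/sinh(s), s = 2π²ρ/b.

    Its edge response along any direction is a logistic of rate ``b_inv_mm``
    (projection-slice: the LSF spectrum equals the OTF along one axis), so a
    perfect measurement recovers exactly the fitted-logistic TTF closed
    form with f50 = 0.110292·b.
    """

    b_inv_mm: float

    def ttf(self, f_inv_mm):
        f = np.asarray(f_inv_mm, dtype=float)
        s = 2 * np.pi**2 * f / self.b_inv_mm
        out = np.ones_like(s)
        nz = s != 0
        out[nz] = s[nz] / np.sinh(np.clip(s[nz], None, 700))
        return out

    def f50(self) -> float:
        return 0.110292 * self.b_inv_mm

    def f10(self) -> float:
        return 0.227953 * self.b_inv_mm

    def support_mm(self) -> float:
        return 25.0 / self.b_inv_mm

    def apply(self, arr, spacing_mm):
        pad = int(np.ceil(self.support_mm() / spacing_mm))
        padded = np.pad(arr, pad, mode="edge")
        fr = np.fft.rfftfreq(padded.shape[1], d=spacing_mm)
        fc = np.fft.fftfreq(padded.shape[0], d=spacing_mm)
        rho = np.hypot(fc[:, None], fr[None, :])
        spec = np.fft.rfft2(padded)
        spec *= self.ttf(rho)
        out = np.fft.irfft2(spec, s=padded.shape)
        return out[pad:-pad, pad:-pad].astype(arr.dtype, copy=False)

    def describe(self) -> dict:
        return {"kind": "logistic", "b_inv_mm": self.b_inv_mm}


@dataclass(frozen=True)
class PinSpec:
    material: str
    center_mm: tuple[float, float]  # (row, col) from image origin
    radius_mm: float
    hu: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom slice.

    ``blur`` is a single kernel for the whole image, or a per-material map
    ``{material: kernel}`` with a ``"body"`` entry for the body outline.
    """

    pins: list[PinSpec]
    body_diameter_mm: float = 200.0
    fov_mm: float = 200.0
    grid_px: int = 512
    background_hu: float = 0.0
    blur: BlurKernel | dict[str, BlurKernel] = field(default_factory=lambda: GaussianBlur(0.5))
    noise_sd_hu: float = 5.0
    seed: int = 0
    supersample: int = 8

    def __post_init__(self) -> None:
        if self.fov_mm < self.body_diameter_mm:
            raise ValueError("fov_mm must be >= body_diameter_mm")
        if self.grid_px < 16 or self.supersample < 1:
            raise ValueError("grid_px/supersample out of range")
        cy = cx = self.fov_mm / 2.0
        R = self.body_diameter_mm / 2.0
        for p in self.pins:
            if np.hypot(p.center_mm[0] - cy, p.center_mm[1] - cx) + p.radius_mm >= R:
                raise ValueError(f"pin {p.material} extends outside the body")
        for i, p in enumerate(self.pins):
            for q in self.pins[i + 1 :]:
                gap = np.hypot(p.center_mm[0] - q.center_mm[0], p.center_mm[1] - q.center_mm[1])
                if gap <= p.radius_mm + q.radius_mm:
                    raise ValueError(f"pins {p.material} and {q.material} overlap")

    @property
    def spacing_mm(self) -> float:
        return self.fov_mm / self.grid_px

    def kernel_for(self, material: str | None) -> BlurKernel:
        if isinstance(self.blur, dict):
            if material is not None and material in self.blur:
                return self.blur[material]
            return self.blur.get("body", NoBlur())
        return self.blur


@dataclass
class GroundTruth:
    """Exact generating parameters of a rendered phantom."""

    body_center_mm: tuple[float, float]
    body_diameter_mm: float
    spacing_mm: float
    noise_sd_hu: float
    seed: int
    pins: list[dict]

    def pin(self, material: str) -> dict:
        for p in self.pins:
            if p["material"] == material:
                return p
        raise KeyError(material)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def _disk_fill(
    arr: np.ndarray, spacing: float, center: tuple[float, float], radius: float, value: float
) -> None:
    """Set arr to ``value`` inside a disk; arr pixels are centred at
    (i+0.5)·spacing.  Operates in-place on a bounding-box window."""
    r0 = max(int((center[0] - radius) / spacing) - 1, 0)
    r1 = min(int((center[0] + radius) / spacing) + 2, arr.shape[0])
    c0 = max(int((center[1] - radius) / spacing) - 1, 0)
    c1 = min(int((center[1] + radius) / spacing) + 2, arr.shape[1])
    rr = (np.arange(r0, r1) + 0.5) * spacing - center[0]
    cc = (np.arange(c0, c1) + 0.5) * spacing - center[1]
    inside = rr[:, None] ** 2 + cc[None, :] ** 2 <= radius**2
    win = arr[r0:r1, c0:c1]
    win[inside] = value


def render(spec: PhantomSpec) -> tuple[HUImage, GroundTruth]:
    """Rasterize, blur, sample and add noise; return image + ground truth."""
    S = spec.supersample
    n_ss = spec.grid_px * S
    sp_ss = spec.fov_mm / n_ss
    center = (spec.fov_mm / 2.0, spec.fov_mm / 2.0)

    per_pin = isinstance(spec.blur, dict)
    geo = np.full((n_ss, n_ss), -1000.0, dtype=np.float32)
    _disk_fill(geo, sp_ss, center, spec.body_diameter_mm / 2.0, spec.background_hu)
    if not per_pin:
        for p in spec.pins:
            _disk_fill(geo, sp_ss, p.center_mm, p.radius_mm, p.hu)
        blurred = spec.kernel_for(None).apply(geo, sp_ss)
    else:
        blurred = spec.kernel_for(None).apply(geo, sp_ss)
        for p in spec.pins:
            k = spec.kernel_for(p.material)
            half = p.radius_mm + k.support_mm() + 2.0
            r0 = max(int((p.center_mm[0] - half) / sp_ss), 0)
            r1 = min(int((p.center_mm[0] + half) / sp_ss) + 1, n_ss)
            c0 = max(int((p.center_mm[1] - half) / sp_ss), 0)
            c1 = min(int((p.center_mm[1] + half) / sp_ss) + 1, n_ss)
            delta = np.zeros((r1 - r0, c1 - c0), dtype=np.float32)
            local_center = (p.center_mm[0] - r0 * sp_ss, p.center_mm[1] - c0 * sp_ss)
            _disk_fill(delta, sp_ss, local_center, p.radius_mm, p.hu - spec.background_hu)
            blurred[r0:r1, c0:c1] += k.apply(delta, sp_ss)

    if S == 1:
        img = blurred.astype(float)
    else:
        # sample at pixel centres: mean of the central 2x2 subsamples
        o2 = S // 2
        o1 = o2 - 1 if S % 2 == 0 else o2
        img = 0.25 * (
            blurred[o1::S, o1::S].astype(float)
            + blurred[o1::S, o2::S]
            + blurred[o2::S, o1::S]
            + blurred[o2::S, o2::S]
        )

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + spec.noise_sd_hu * rng.standard_normal(img.shape)

    spacing = spec.spacing_mm
    truth = GroundTruth(
        body_center_mm=center,
        body_diameter_mm=spec.body_diameter_mm,
        spacing_mm=spacing,
        noise_sd_hu=spec.noise_sd_hu,
        seed=spec.seed,
        pins=[
            {
                "material": p.material,
                "center_mm": p.center_mm,
                "radius_mm": p.radius_mm,
                "hu": p.hu,
                "kernel": spec.kernel_for(p.material).describe(),
                "f50_inv_mm": spec.kernel_for(p.material).f50(),
                "f10_inv_mm": spec.kernel_for(p.material).f10(),
            }
            for p in spec.pins
        ],
    )
    return HUImage(pixels=img, spacing_mm=(spacing, spacing)), truth


# --- presets -----------------------------------------------------------------

_PRESET_TEMPLATE = {"acr_like": "computational_acr", "aapm_like": "aapm", "catphan_like": "catphan604"}

# AAPM pins: distinct HU values inside each material's window, chosen so the
# overlapping acrylic/polycarbonate/nylon windows genuinely require angular
# disambiguation (polycarbonate at 107 HU sits inside all three windows).
_AAPM_HU = {
    "Acrylic": 140.0,
    "Polycarbonate": 107.0,
    "Polyethylene": -85.0,
    "Polystyrene": -37.0,
    "Nylon": 90.0,
}


def preset_names() -> list[str]:
    return sorted(_PRESET_TEMPLATE)


def preset(name: str, **overrides) -> PhantomSpec:
    """A ready-made phantom spec for one of the three synthetic layouts.

    Pin coordinates are plausible synthetic layouts (radius-60 mm ring at
    the template's expected angles), not the physical phantoms' engineering
    drawings.  Material HU values sit at the documented nominal CT numbers
    (mid-window where no nominal is documented).  Overrides pass through to
    :class:`PhantomSpec` (``blur=``, ``noise_sd_hu=``, ``seed=`` ...).
    """
    if name not in _PRESET_TEMPLATE:
        raise KeyError(f"unknown preset {name!r}; valid: {', '.join(preset_names())}")
    template = get_template(_PRESET_TEMPLATE[name])
    body = overrides.get("body_diameter_mm", 200.0)
    fov = overrides.get("fov_mm", 200.0)
    layout_radius = 60.0 * body / 200.0
    pin_radius = 12.5 * body / 200.0
    cy = cx = fov / 2.0
    pins = []
    for w in template.windows:
        ang = math.radians(w.expected_angle_deg or 0.0)
        row = cy - layout_radius * math.sin(ang)
        col = cx + layout_radius * math.cos(ang)
        if w.nominal_hu is not None:
            hu = w.nominal_hu
        elif name == "aapm_like":
            hu = _AAPM_HU[w.material_name]
        else:
            lo = w.lower_hu if math.isfinite(w.lower_hu) else w.upper_hu - 200
            hi = w.upper_hu if math.isfinite(w.upper_hu) else w.lower_hu + 200
            hu = 0.5 * (lo + hi)
        pins.append(PinSpec(w.material_name, (row, col), pin_radius, hu))
    kwargs = dict(overrides)
    kwargs.pop("body_diameter_mm", None)
    kwargs.pop("fov_mm", None)
    return PhantomSpec(pins=pins, body_diameter_mm=body, fov_mm=fov, **kwargs)
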