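"""Phantom templates: pin materials and HU segmentation windows.

Four multi-pin phantom families are registered: a computational phantom
modelled on the ACR 464, the physical ACR 464, the AAPM CT performance
phantom, and the Catphan 604 sensitometry module.  Each template lists the
pin materials with the HU threshold window used to segment each pin, the
expected pin count (4/4/5/9), and the body-segmentation threshold.

Windows may legitimately overlap (on the AAPM phantom, acrylic,
polycarbonate and nylon share most of their HU range); such materials carry
an expected polar angle so segmentation can disambiguate them by position.

Templates serialize to YAML so users can register vendor-specific phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "MaterialWindow",
    "PhantomTemplate",
    "get_template",
    "classify_hu",
    "template_names",
]


@dataclass(frozen=True)
class MaterialWindow:
    """One pin material's segmentation window.

    ``lower_hu``/``upper_hu`` may be ``-inf``/``+inf`` for one-sided windows
    (printed as "None" in phantom documentation).  ``nominal_hu`` is the
    expected CT number where documented.  ``expected_angle_deg`` is the
    approximate polar angle of the pin about the phantom centre (math
    convention: CCW from +x with +y up), used only to disambiguate materials
    whose windows overlap.
    """

    material_name: str
    lower_hu: float
    upper_hu: float
    nominal_hu: float | None = None
    expected_angle_deg: float | None = None

    def __post_init__(self) -> None:
        lo, hi = float(self.lower_hu), float(self.upper_hu)
        if not (math.isfinite(lo) or math.isfinite(hi)):
            raise ValueError(f"{self.material_name}: window must be bounded on at least one side")
        if lo >= hi:
            raise ValueError(f"{self.material_name}: lower_hu {lo} must be < upper_hu {hi}")

    def contains(self, hu: float) -> bool:
        return self.lower_hu <= hu <= self.upper_hu


@dataclass(frozen=True)
class PhantomTemplate:
    """A named phantom family with its material windows."""

    name: str
    windows: tuple[MaterialWindow, ...]
    body_threshold_hu: float = -200.0
    nominal_pin_radius_mm: float = 12.5

    def __post_init__(self) -> None:
        names = [w.material_name for w in self.windows]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: duplicate material names in {names}")
        if not self.windows:
            raise ValueError(f"{self.name}: template has no material windows")

    @property
    def expected_pin_count(self) -> int:
        return len(self.windows)

    def window(self, material_name: str) -> MaterialWindow:
        for w in self.windows:
            if w.material_name == material_name:
                return w
        raise KeyError(f"{self.name}: no material named {material_name!r}")

    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "name": self.name,
            "body_threshold_hu": self.body_threshold_hu,
            "nominal_pin_radius_mm": self.nominal_pin_radius_mm,
            "windows": [
                {
                    "material_name": w.material_name,
                    "lower_hu": None if not math.isfinite(w.lower_hu) else w.lower_hu,
                    "upper_hu": None if not math.isfinite(w.upper_hu) else w.upper_hu,
                    "nominal_hu": w.nominal_hu,
                    "expected_angle_deg": w.expected_angle_deg,
                }
                for w in self.windows
            ],
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomTemplate":
        doc = yaml.safe_load(Path(path).read_text())
        windows = tuple(
            MaterialWindow(
                material_name=w["material_name"],
                lower_hu=-math.inf if w.get("lower_hu") is None else float(w["lower_hu"]),
                upper_hu=math.inf if w.get("upper_hu") is None else float(w["upper_hu"]),
                nominal_hu=w.get("nominal_hu"),
                expected_angle_deg=w.get("expected_angle_deg"),
            )
            for w in doc["windows"]
        )
        return cls(
            name=doc["name"],
            windows=windows,
            body_threshold_hu=float(doc.get("body_threshold_hu", -200.0)),
            nominal_pin_radius_mm=float(doc.get("nominal_pin_radius_mm", 12.5)),
        )


_INF = math.inf

# ACR 464-style module: 4 pins.  One-sided windows are printed "None" in the
# phantom documentation and map to an unbounded side here.
_ACR_WINDOWS = (
    MaterialWindow("Bone", 750.0, 1300.0, nominal_hu=955.0, expected_angle_deg=90.0),
    MaterialWindow("Polyethylene", -120.0, -70.0, nominal_hu=-95.0, expected_angle_deg=0.0),
    MaterialWindow("Air", -_INF, -800.0, nominal_hu=-1000.0, expected_angle_deg=270.0),
    MaterialWindow("Acrylic", 100.0, 150.0, nominal_hu=120.0, expected_angle_deg=180.0),
)

# AAPM CT performance phantom: 5 pins.  No nominal CT numbers are documented
# for this module; acrylic/polycarbonate/nylon windows overlap, so expected
# angles carry the disambiguation.
_AAPM_WINDOWS = (
    MaterialWindow("Acrylic", 80.0, 165.0, expected_angle_deg=90.0),
    MaterialWindow("Polycarbonate", 100.0, 114.0, expected_angle_deg=162.0),
    MaterialWindow("Polyethylene", -110.0, -60.0, expected_angle_deg=234.0),
    MaterialWindow("Polystyrene", -55.0, -20.0, expected_angle_deg=306.0),
    MaterialWindow("Nylon", 80.0, 115.0, expected_angle_deg=18.0),
)

# Catphan 604 sensitometry module: 9 pins.  The documented Delrin CT-number
# range cell is internally inconsistent ("344 to 37"); the operative values
# are the threshold columns (300–430), which are what this registry stores.
_CATPHAN_WINDOWS = (
    MaterialWindow("Air", -_INF, -900.0, nominal_hu=-1016.0, expected_angle_deg=90.0),
    MaterialWindow("PMP", -250.0, -160.0, nominal_hu=-196.0, expected_angle_deg=130.0),
    MaterialWindow("LDPE", -121.0, -87.0, nominal_hu=-104.0, expected_angle_deg=170.0),
    MaterialWindow("Polystyrene", -65.0, -10.0, nominal_hu=-47.0, expected_angle_deg=210.0),
    MaterialWindow("Acrylic", 80.0, 150.0, nominal_hu=115.0, expected_angle_deg=250.0),
    MaterialWindow("Bone 20%", 200.0, 280.0, nominal_hu=237.0, expected_angle_deg=290.0),
    MaterialWindow("Delrin", 300.0, 430.0, nominal_hu=365.0, expected_angle_deg=330.0),
    MaterialWindow("Bone 50%", 600.0, 800.0, nominal_hu=725.0, expected_angle_deg=10.0),
    MaterialWindow("Teflon", 900.0, _INF, nominal_hu=1000.0, expected_angle_deg=50.0),
)

_REGISTRY: dict[str, PhantomTemplate] = {
    "computational_acr": PhantomTemplate("computational_acr", _ACR_WINDOWS),
    "acr464": PhantomTemplate("acr464", _ACR_WINDOWS),
    "aapm": PhantomTemplate("aapm", _AAPM_WINDOWS),
    "catphan604": PhantomTemplate("catphan604", _CATPHAN_WINDOWS),
}


def template_names() -> list[str]:
    return sorted(_REGISTRY)


def get_template(name: str) -> PhantomTemplate:
    """Look up a registered phantom template by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists valid names.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown phantom template {name!r}; valid names: {', '.join(template_names())}"
        ) from None


def classify_hu(template: PhantomTemplate, hu: float) -> set[str]:
    """Every material whose window contains ``hu`` (windows may overlap)."""
    return {w.material_name for w in template.windows if w.contains(hu)}
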