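"""Batch measurement driver and tabular reporting.

`run` executes the full pipeline — body segmentation, masking, pin
segmentation, ROI placement, ESF→TTF — on one DICOM file or a directory of
them, and collects one row per measured pin (CNR, f50, f10, fit RMSE,
flags) plus a failure manifest.  Reports serialize to CSV (stable, versioned
column schema; deterministic bytes for identical input/config) and JSON
(adds full TTF curves and provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .esf_ttf import TTFConfig, TTFResult, measure_ttf
from .image_io import HUImage, load_slice
from .phantom_model import get_template
from .segmentation import (
    PinROI,
    SegmentationError,
    apply_body_mask,
    place_rois,
    segment_body,
    segment_pins,
)

log = logging.getLogger(__name__)

CSV_SCHEMA_VERSION = 1
CSV_COLUMNS = [
    "schema_version",
    "source",
    "phantom",
    "material",
    "inner_mean_hu",
    "outer_mean_hu",
    "outer_sd_hu",
    "cnr",
    "f50_inv_mm",
    "f10_inv_mm",
    "fit_rmse_hu",
    "flags",
]

__all__ = ["SliceMeasurement", "RunReport", "measure_slice", "run"]


@dataclass
class SliceMeasurement:
    """All per-pin results for one slice."""

    source: str
    phantom: str
    body_diameter_mm: float
    rois: list[PinROI]
    results: list[TTFResult]
    failures: list[tuple[str, str]]


@dataclass
class RunReport:
    phantom: str
    config: TTFConfig
    slices: list[SliceMeasurement] = field(default_factory=list)

    @property
    def all_succeeded(self) -> bool:
        return all(not s.failures for s in self.slices) and bool(self.slices)

    def rows(self) -> pd.DataFrame:
        recs = []
        for s in self.slices:
            roi_by_name = {r.material_name: r for r in s.rois}
            for res in s.results:
                roi = roi_by_name[res.material_name]
                recs.append(
                    {
                        "schema_version": CSV_SCHEMA_VERSION,
                        "source": s.source,
                        "phantom": s.phantom,
                        "material": res.material_name,
                        "inner_mean_hu": roi.inner_mean_hu,
                        "outer_mean_hu": roi.outer_mean_hu,
                        "outer_sd_hu": roi.outer_sd_hu,
                        "cnr": res.cnr,
                        "f50_inv_mm": res.f50_inv_mm,
                        "f10_inv_mm": res.f10_inv_mm,
                        "fit_rmse_hu": res.fit_rmse_hu,
                        "flags": ";".join(res.flags),
                    }
                )
        return pd.DataFrame(recs, columns=CSV_COLUMNS)

    def config_hash(self) -> str:
        blob = json.dumps(self.config.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows().to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        return path

    def write_json(self, path: str | Path) -> Path:
        doc = {
            "software": "cttf",
            "version": __version__,
            "phantom": self.phantom,
            "config": self.config.to_dict(),
            "config_hash": self.config_hash(),
            "slices": [
                {
                    "source": s.source,
                    "body_diameter_mm": s.body_diameter_mm,
                    "failures": [{"material": m, "reason": r} for m, r in s.failures],
                    "pins": [
                        {
                            "material": res.material_name,
                            "cnr": _jsonable(res.cnr),
                            "f50_inv_mm": _jsonable(res.f50_inv_mm),
                            "f10_inv_mm": _jsonable(res.f10_inv_mm),
                            "fit_rmse_hu": _jsonable(res.fit_rmse_hu),
                            "flags": res.flags,
                            "frequencies_inv_mm": res.frequencies_inv_mm[:: max(1, len(res.frequencies_inv_mm) // 512)].tolist(),
                            "ttf": res.ttf[:: max(1, len(res.ttf) // 512)].tolist(),
                        }
                        for res in s.results
                    ],
                }
                for s in self.slices
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=2))
        return path


def _jsonable(x: float):
    return None if not np.isfinite(x) else float(x)


def measure_slice(
    img: HUImage, phantom: str, config: TTFConfig | None = None, source: str = "<memory>"
) -> SliceMeasurement:
    """Run the two-stage pipeline on one in-memory HU image."""
    config = config or TTFConfig()
    template = get_template(phantom)
    body = segment_body(img, template.body_threshold_hu)
    log.info("%s: body diameter %.1f mm", source, body.diameter_mm)
    masked = apply_body_mask(img, body)
    try:
        pins = segment_pins(masked, body, template)
        rois = place_rois(masked, body, pins)
    except SegmentationError as exc:
        return SliceMeasurement(source, phantom, body.diameter_mm, [], [], [("<segmentation>", str(exc))])
    results, failures = measure_ttf(masked, rois, config)
    log.info("%s: %d pins measured, %d failed", source, len(results), len(failures))
    return SliceMeasurement(source, phantom, body.diameter_mm, rois, results, failures)


def run(
    input_path: str | Path,
    phantom: str,
    config: TTFConfig | None = None,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> RunReport:
    """Measure every DICOM slice at ``input_path`` (file or directory).

    Slices in a directory are processed in filename order, independently (no
    inter-slice averaging).  When ``out_dir`` is given, CSV and JSON reports
    (and optional plots) are written there.
    """
    config = config or TTFConfig()
    input_path = Path(input_path)
    if input_path.is_dir():
        files = sorted(p for p in input_path.iterdir() if p.is_file())
    else:
        files = [input_path]
    if not files:
        raise FileNotFoundError(f"no input files under {input_path}")

    report = RunReport(phantom=phantom, config=config)
    for f in files:
        img = load_slice(f)
        report.slices.append(measure_slice(img, phantom, config, source=f.name))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.write_csv(out_dir / "ttf_report.csv")
        report.write_json(out_dir / "ttf_report.json")
        if plots:
            from .plotting import plot_report

            plot_report(report, [load_slice(f) for f in files], out_dir)
    return report
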