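"""Optional diagnostic plots: ROI overlays and TTF curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .image_io import HUImage
from .report import RunReport


def plot_report(report: RunReport, images: list[HUImage], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for meas, img in zip(report.slices, images):
        stem = Path(meas.source).stem or "slice"

        fig, ax = plt.subplots(figsize=(6, 6))
        sr, sc = img.spacing_mm
        ax.imshow(img.pixels, cmap="gray", vmin=-200, vmax=200,
                  extent=(0, img.shape[1] * sc, img.shape[0] * sr, 0))
        for roi in meas.rois:
            y, x = roi.centroid_mm
            ax.add_patch(Circle((x, y), roi.roi_diameter_mm / 2, fill=False, color="lime", lw=1.2))
            ax.add_patch(Circle((x, y), roi.pin_radius_mm, fill=False, color="gold", lw=0.8, ls="--"))
            ax.add_patch(Circle((x, y), 1.5 * roi.pin_radius_mm, fill=False, color="gold", lw=0.8, ls="--"))
            ax.annotate(roi.material_name, (x, y - roi.pin_radius_mm - 2),
                        color="w", fontsize=7, ha="center")
        ax.set_title(f"{meas.phantom}: ROI placement ({meas.source})")
        ax.set_xlabel("mm")
        p = out_dir / f"{stem}_rois.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

        if meas.results:
            fig, ax = plt.subplots(figsize=(6, 4))
            for res in meas.results:
                m = res.frequencies_inv_mm <= 1.5
                ax.plot(res.frequencies_inv_mm[m], res.ttf[m],
                        label=f"{res.material_name} (f50={res.f50_inv_mm:.2f})")
            ax.axhline(0.5, color="gray", lw=0.5, ls=":")
            ax.axhline(0.1, color="gray", lw=0.5, ls=":")
            ax.set_xlabel("spatial frequency (mm$^{-1}$)")
            ax.set_ylabel("TTF")
            ax.set_ylim(0, 1.05)
            ax.legend(fontsize=7)
            ax.set_title(f"{meas.phantom}: TTF ({meas.source})")
            p = out_dir / f"{stem}_ttf.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(p)
    return written
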