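"""DICOM I/O for single axial CT slices.

CT images are exchanged as single-frame DICOM files whose stored integers map
to Hounsfield units (HU) through ``RescaleSlope``/``RescaleIntercept`` and
whose spatial calibration lives in ``PixelSpacing`` (mm).  This module reads
such files into :class:`HUImage` — a plain HU raster with pixel spacing —
and writes HU rasters back out as CT DICOM, quantizing to 16-bit integers
(round-trip error ≤ 0.5 HU for the CT range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = ["HUImage", "CalibrationError", "FormatError", "load_slice", "save_slice"]


class CalibrationError(ValueError):
    """Required spatial/intensity calibration metadata is missing."""


class FormatError(ValueError):
    """Input is not a readable single-frame CT-like DICOM image."""


@dataclass
class HUImage:
    """A 2-D raster of Hounsfield units with spatial calibration.

    Parameters
    ----------
    pixels
        2-D float array of HU values (rescale already applied).
    spacing_mm
        Pixel size in mm as (row, col).  Non-square spacing is accepted with
        a warning; downstream radial distances honour the anisotropy.
    origin_mm
        Physical position of pixel (0, 0) in mm, default (0, 0).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        sr, sc = float(self.spacing_mm[0]), float(self.spacing_mm[1])
        if sr <= 0 or sc <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing_mm}")
        self.spacing_mm = (sr, sc)
        if abs(sr - sc) > 1e-9:
            warnings.warn(
                f"non-square pixel spacing {self.spacing_mm}; radial distances "
                "will use anisotropic scaling",
                stacklevel=3,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the raster in mm."""
        return (
            self.shape[0] * self.spacing_mm[0],
            self.shape[1] * self.spacing_mm[1],
        )

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates of every pixel centre, as (row_mm, col_mm) grids."""
        r = self.origin_mm[0] + (np.arange(self.shape[0]) + 0.5) * self.spacing_mm[0]
        c = self.origin_mm[1] + (np.arange(self.shape[1]) + 0.5) * self.spacing_mm[1]
        return np.meshgrid(r, c, indexing="ij")


def load_slice(path: str | Path) -> HUImage:
    """Read a single-frame CT DICOM file into an :class:`HUImage`.

    Stored values are mapped to HU via ``stored * RescaleSlope +
    RescaleIntercept``; pixel spacing comes from ``PixelSpacing``.

    Raises
    ------
    FormatError
        If the file is not a DICOM image with pixel data.
    CalibrationError
        If pixel spacing or the rescale tags are absent.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several types for bad input
        raise FormatError(f"{path} is not a readable DICOM file: {exc}") from exc
    if "PixelData" not in ds:
        raise FormatError(f"{path} contains no pixel data")
    if "PixelSpacing" not in ds:
        raise CalibrationError(f"{path} has no PixelSpacing tag; spatial calibration unknown")
    if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
        raise CalibrationError(f"{path} lacks RescaleSlope/RescaleIntercept; HU calibration unknown")
    stored = ds.pixel_array
    if stored.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame image, got shape {stored.shape}")
    hu = stored.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    meta = {"path": str(path)}
    for tag in ("SOPInstanceUID", "SeriesInstanceUID", "Modality"):
        if tag in ds:
            meta[tag] = str(getattr(ds, tag))
    return HUImage(pixels=hu, spacing_mm=spacing, meta=meta)


def save_slice(img: HUImage, path: str | Path) -> Path:
    """Write an :class:`HUImage` as a single-frame CT DICOM file.

    HU values are stored as signed 16-bit integers with slope 1 and
    intercept −1024 (the conventional CT encoding), so the reload error is
    bounded by integer quantization (≤ 0.5 HU).
    """
    path = Path(path)
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = CTImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Modality = "CT"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"

    intercept = -1024.0
    stored = np.round(img.pixels - intercept)
    stored = np.clip(stored, -32768, 32767).astype(np.int16)
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [f"{img.spacing_mm[0]:.6f}", f"{img.spacing_mm[1]:.6f}"]
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = f"{intercept:.0f}"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.PixelData = stored.tobytes()

    try:
        ds.save_as(path, enforce_file_format=True)
    except OSError as exc:
        raise OSError(f"cannot write DICOM to {path}: {exc}") from exc
    return path
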