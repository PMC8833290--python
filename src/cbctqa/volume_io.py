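"""Shared spatial data model and volume/table I/O.

Conventions used by every metric module
---------------------------------------
* Voxel array axis order is ``(slice, row, column)``; the row axis runs
  anterior -> posterior and the column axis runs across the patient
  (lateral).  Values are CT-numbers in HU, stored as floating point.
* ``spacing = (dx, dy, dz)`` in mm, where ``dx`` is the in-plane column
  (lateral) pitch, ``dy`` the in-plane row pitch and ``dz`` the slice pitch.
* All physical coordinates are millimetres.  The origin is the position of
  the *center* of voxel ``(0, 0, 0)``; the center of pixel ``(row i, col j)``
  therefore sits at ``(origin_y + i*dy, origin_x + j*dx)``.
* A pixel belongs to a circular ROI iff its center lies strictly inside the
  circle; ROI standard deviations are population SDs (divide by n).

Supported formats: DICOM series (one file per slice, RescaleSlope/Intercept
honoured), NIfTI-1, and a raw float64 + JSON-metadata fallback.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .exceptions import BoundsError, FormatError, GeometryError

__all__ = [
    "ImageVolume",
    "CircularROI",
    "RectROI",
    "ROIStats",
    "read_volume",
    "write_volume",
    "extract_roi_stats",
    "circular_mask",
    "rect_slices",
    "read_roi_table",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D HU grid with spacing and origin metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        CT-numbers in HU, finite floats.
    spacing : (dx, dy, dz)
        Strictly positive voxel pitch in mm (column, row, slice).
    origin : (x0, y0, z0)
        mm position of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError("voxels must be a 3D array with all dims >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (row_mm, col_mm) coordinate vectors of in-plane pixel centers."""
        dx, dy, _ = self.spacing
        _, ny, nx = self.voxels.shape
        rows = self.origin[1] + np.arange(ny) * dy
        cols = self.origin[0] + np.arange(nx) * dx
        return rows, cols

    def get_slice(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_slices:
            raise BoundsError(f"slice index {index} outside volume with {self.n_slices} slices")
        return self.voxels[index]


@dataclass(frozen=True)
class CircularROI:
    """Circular region on one axial slice; center (row, col) and radius in mm."""

    slice_index: int
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise BoundsError("circular ROI radius must be positive")


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle on one axial slice; corner (row, col), extent (h, w) mm."""

    slice_index: int
    corner: tuple[float, float]
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.extent) <= 0:
            raise BoundsError("rect ROI extent must be positive")


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n_pixels: int


# --------------------------------------------------------------------------
# ROI machinery
# --------------------------------------------------------------------------

def circular_mask(vol: ImageVolume, roi: CircularROI) -> np.ndarray:
    """Boolean in-plane membership mask: pixel centers strictly inside the circle."""
    rows, cols = vol.slice_grid_mm()
    rr = rows - roi.center[0]
    cc = cols - roi.center[1]
    dist2 = rr[:, None] ** 2 + cc[None, :] ** 2
    return dist2 < roi.radius ** 2


def rect_slices(vol: ImageVolume, roi: RectROI) -> tuple[slice, slice]:
    """Pixel-index slices of the rectangle (pixels whose centers fall inside)."""
    dx, dy, _ = vol.spacing
    r0 = int(math.ceil((roi.corner[0] - vol.origin[1]) / dy - 0.5))
    c0 = int(math.ceil((roi.corner[1] - vol.origin[0]) / dx - 0.5))
    r1 = int(math.floor((roi.corner[0] + roi.extent[0] - vol.origin[1]) / dy + 0.5))
    c1 = int(math.floor((roi.corner[1] + roi.extent[1] - vol.origin[0]) / dx + 0.5))
    return slice(max(r0, 0), r1), slice(max(c0, 0), c1)


def extract_roi_stats(vol: ImageVolume, roi: Union[CircularROI, RectROI]) -> ROIStats:
    """Mean and population SD over pixels whose centers fall inside the ROI.

    Raises
    ------
    BoundsError
        If the ROI (or its slice index) is not entirely inside the volume.
    """
    img = vol.get_slice(roi.slice_index)
    ny, nx = img.shape
    dx, dy, _ = vol.spacing
    y_max = vol.origin[1] + (ny - 1) * dy
    x_max = vol.origin[0] + (nx - 1) * dx
    if isinstance(roi, CircularROI):
        if (roi.center[0] - roi.radius < vol.origin[1] - dy / 2
                or roi.center[0] + roi.radius > y_max + dy / 2
                or roi.center[1] - roi.radius < vol.origin[0] - dx / 2
                or roi.center[1] + roi.radius > x_max + dx / 2):
            raise BoundsError("circular ROI extends outside the slice")
        values = img[circular_mask(vol, roi)]
    elif isinstance(roi, RectROI):
        if (roi.corner[0] < vol.origin[1] - dy / 2
                or roi.corner[1] < vol.origin[0] - dx / 2
                or roi.corner[0] + roi.extent[0] > y_max + dy / 2
                or roi.corner[1] + roi.extent[1] > x_max + dx / 2):
            raise BoundsError("rect ROI extends outside the slice")
        rs, cs = rect_slices(vol, roi)
        values = img[rs, cs].ravel()
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported ROI type {type(roi)!r}")
    if values.size < 1:
        raise BoundsError("ROI contains no pixel centers")
    return ROIStats(mean=float(values.mean()), sd=float(values.std(ddof=0)),
                    n_pixels=int(values.size))


# --------------------------------------------------------------------------
# Volume I/O
# --------------------------------------------------------------------------

def read_volume(path: Union[str, Path], format: str) -> ImageVolume:
    """Read an image volume; ``format`` is one of dicom_series/nifti/raw_json."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format == "dicom_series":
        return _read_dicom_series(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "raw_json":
        return _read_raw_json(path)
    raise FormatError(f"unknown format {format!r}")


def write_volume(vol: ImageVolume, path: Union[str, Path], format: str) -> Path:
    """Write a volume; DICOM quantizes HU to integers, other formats are lossless."""
    path = Path(path)
    if format == "dicom_series":
        return _write_dicom_series(vol, path)
    if format == "nifti":
        return _write_nifti(vol, path)
    if format == "raw_json":
        return _write_raw_json(vol, path)
    raise FormatError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    # header pixdim is float32; round to nm precision for clean mm values
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"expected 3D NIfTI, got shape {data.shape}")
    # nibabel axis order (x, y, z) -> ours (slice, row, col)
    voxels = np.transpose(data, (2, 1, 0))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels=voxels, spacing=zooms, origin=origin)


def _write_nifti(vol: ImageVolume, path: Path) -> Path:
    dx, dy, dz = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = vol.origin
    data = np.transpose(vol.voxels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def _read_raw_json(path: Path) -> ImageVolume:
    meta = json.loads(Path(path).read_text())
    for key in ("shape", "spacing", "raw_file"):
        if key not in meta:
            raise FormatError(f"raw_json metadata missing attribute {key!r}")
    raw = path.parent / meta["raw_file"]
    voxels = np.fromfile(raw, dtype=np.float64).reshape(meta["shape"])
    return ImageVolume(voxels=voxels, spacing=tuple(meta["spacing"]),
                       origin=tuple(meta.get("origin", (0.0, 0.0, 0.0))))


def _write_raw_json(vol: ImageVolume, path: Path) -> Path:
    path = path.with_suffix(".json")
    raw = path.with_suffix(".raw")
    vol.voxels.astype(np.float64).tofile(raw)
    meta = {"shape": list(vol.voxels.shape), "spacing": list(vol.spacing),
            "origin": list(vol.origin), "raw_file": raw.name, "dtype": "float64",
            "axis_order": "slice,row,col", "units": "HU"}
    path.write_text(json.dumps(meta, indent=1))
    return path


def _read_dicom_series(path: Path) -> ImageVolume:
    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    ref = datasets[0]
    for attr in ("PixelSpacing", "Rows", "Columns", "ImageOrientationPatient"):
        ref_val = getattr(ref, attr, None)
        if ref_val is None:
            raise FormatError(f"DICOM slice missing attribute {attr}")
        for ds in datasets[1:]:
            if getattr(ds, attr, None) != ref_val:
                raise FormatError(f"heterogeneous DICOM attribute {attr}")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        gaps = np.diff(zs)
        dz = float(np.mean(gaps))
        if dz <= 0 or np.any(np.abs(gaps - dz) > 0.01 * abs(dz)):
            raise GeometryError(f"non-uniform slice gap beyond 1%: {gaps}")
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    # DICOM PixelSpacing is (row pitch, col pitch)
    dy, dx = (float(v) for v in ref.PixelSpacing)
    ipp = ref.ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(zs[0]))
    return ImageVolume(voxels=np.stack(slices), spacing=(dx, dy, dz), origin=origin)


def _write_dicom_series(vol: ImageVolume, path: Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dx, dy, dz = vol.spacing
    series_uid = generate_uid()
    stored = np.rint(vol.voxels).astype(np.int16)
    for k in range(vol.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]
        ds.SliceThickness = f"{dz:.6f}"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [f"{vol.origin[0]:.6f}", f"{vol.origin[1]:.6f}",
                                   f"{vol.origin[2] + k * dz:.6f}"]
        ds.InstanceNumber = k + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = stored[k].tobytes()
        ds.save_as(str(path / f"slice_{k:04d}.dcm"), enforce_file_format=True)
    return path


# --------------------------------------------------------------------------
# Tabular ROI input
# --------------------------------------------------------------------------

def read_roi_table(path: Union[str, Path]) -> list[Union[CircularROI, RectROI]]:
    """Read ROI definitions from a CSV with a header row.

    Columns: ``kind`` (circle|rect), ``slice_index``, ``row_mm``, ``col_mm``
    plus ``radius_mm`` for circles or ``height_mm``/``width_mm`` for rects.
    """
    df = pd.read_csv(path)
    rois: list[Union[CircularROI, RectROI]] = []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip().lower()
        if kind == "circle":
            rois.append(CircularROI(int(row["slice_index"]),
                                    (float(row["row_mm"]), float(row["col_mm"])),
                                    float(row["radius_mm"])))
        elif kind == "rect":
            rois.append(RectROI(int(row["slice_index"]),
                                (float(row["row_mm"]), float(row["col_mm"])),
                                (float(row["height_mm"]), float(row["width_mm"]))))
        else:
            raise FormatError(f"unknown ROI kind {kind!r}")
    return rois
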