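"""3-D SUV volume container and I/O (NIfTI, DICOM PET series).

The standardized uptake value (SUV) normalizes tissue activity concentration
to the decay-corrected injected dose and the patient's body weight:

    SUV = C [Bq/ml] * weight [g] / dose_at_scan [Bq]

so a uniform distribution of tracer over the whole body would give SUV = 1
everywhere.  All downstream stages (segmentation, texture) consume this
dimensionless grid together with its physical voxel spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class VolumeError(ValueError):
    """Raised when a volume or its metadata is invalid or unreadable."""


@dataclass
class PETVolume:
    """A 3-D grid of body-weight SUV values with physical voxel spacing.

    Parameters
    ----------
    suv : ndarray, shape (nz, ny, nx)
        Non-negative, finite SUV values.
    spacing_mm : tuple of float
        Voxel edge lengths in mm for each axis, same order as ``suv`` axes.
    patient_id : str, optional
        Identifier carried through feature tables.
    """

    suv: np.ndarray
    spacing_mm: tuple[float, float, float] = (4.06, 4.06, 5.0)
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=np.float64)
        if self.suv.ndim != 3 or self.suv.size == 0:
            raise VolumeError("suv grid must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.suv)):
            raise VolumeError("suv grid contains non-finite values")
        if np.any(self.suv < 0):
            raise VolumeError("suv grid contains negative values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeError("voxel spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.suv.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def write_nifti(volume: PETVolume, path: str | os.PathLike) -> Path:
    """Write a volume as NIfTI-1 with spacing stored in the header zooms."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.suv.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | os.PathLike, patient_id: Optional[str] = None) -> PETVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse error types
        raise VolumeError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return PETVolume(data, tuple(float(z) for z in zooms), patient_id=patient_id)


_DICOM_TM_FMT = "radiopharmaceutical/acquisition times as DICOM TM strings"


def _parse_dicom_time(tm: str) -> float:
    """DICOM TM 'HHMMSS[.ffffff]' -> seconds since midnight."""
    tm = str(tm).strip()
    if len(tm) < 6:
        raise VolumeError(f"malformed DICOM time {tm!r}; expected {_DICOM_TM_FMT}")
    h, m = int(tm[0:2]), int(tm[2:4])
    s = float(tm[4:])
    return 3600.0 * h + 60.0 * m + s


def read_dicom_series(directory: str | os.PathLike,
                      patient_id: Optional[str] = None) -> PETVolume:
    """Read a single-frame PET DICOM series and convert it to body-weight SUV.

    Requires BQML-calibrated slices plus the tags needed for the SUV formula:
    PatientWeight and, inside RadiopharmaceuticalInformationSequence,
    RadionuclideTotalDose, RadiopharmaceuticalStartTime and
    RadionuclideHalfLife.  The injected dose is decay-corrected from injection
    to AcquisitionTime (falling back to SeriesTime).

    Raises
    ------
    VolumeError
        Listing every missing tag, or on non-uniform slice spacing.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue  # skip non-DICOM clutter
    if not datasets:
        raise VolumeError(f"no readable DICOM files in {directory}")

    def z_of(ds):
        return float(ds.ImagePositionPatient[2])

    datasets.sort(key=z_of)
    ref = datasets[0]

    missing = [name for name in ("PatientWeight", "PixelSpacing", "Units")
               if getattr(ref, name, None) is None]
    rpis = getattr(ref, "RadiopharmaceuticalInformationSequence", None)
    if not rpis:
        missing.append("RadiopharmaceuticalInformationSequence")
        rp = None
    else:
        rp = rpis[0]
        for name in ("RadionuclideTotalDose", "RadiopharmaceuticalStartTime",
                     "RadionuclideHalfLife"):
            if getattr(rp, name, None) is None:
                missing.append(name)
    scan_time = getattr(ref, "AcquisitionTime", None) or getattr(ref, "SeriesTime", None)
    if scan_time is None:
        missing.append("AcquisitionTime/SeriesTime")
    if missing:
        raise VolumeError(
            "DICOM series lacks tags required for SUV conversion: "
            + ", ".join(missing))
    if str(ref.Units).strip().upper() != "BQML":
        raise VolumeError(f"expected BQML-calibrated PET data, got Units={ref.Units!r}")

    if len(datasets) > 1:
        zs = np.array([z_of(ds) for ds in datasets])
        dz = np.diff(zs)
        if dz.min() <= 0 or (dz.max() - dz.min()) > 1e-3 * dz.mean():
            raise VolumeError("non-uniform or degenerate slice spacing in DICOM series")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(ref, "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    conc = np.stack(slices, axis=0)  # Bq/ml

    weight_g = float(ref.PatientWeight) * 1000.0
    dose_bq = float(rp.RadionuclideTotalDose)
    half_life_s = float(rp.RadionuclideHalfLife)
    dt = _parse_dicom_time(scan_time) - _parse_dicom_time(rp.RadiopharmaceuticalStartTime)
    if dt < 0:
        dt += 86400.0  # scan past midnight
    dose_at_scan = dose_bq * 2.0 ** (-dt / half_life_s)
    suv = np.clip(conc * weight_g / dose_at_scan, 0.0, None)

    row_mm, col_mm = (float(v) for v in ref.PixelSpacing)
    spacing = (slice_spacing, row_mm, col_mm)
    return PETVolume(suv, spacing, patient_id=patient_id)


def read_volume(path: str | os.PathLike, patient_id: Optional[str] = None) -> PETVolume:
    """Read a PET volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path, patient_id=patient_id)
    return read_nifti(path, patient_id=patient_id)
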