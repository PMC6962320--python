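"""CT volume container and file IO.

Volumes are stored with voxel array axis order (x, y, z) = (left-right,
anterior-posterior, inferior-superior) and 0-based voxel indices.
Attenuation is in Hounsfield units (HU): air = -1000, water = 0.

SimpleITK backs all on-disk formats (NIfTI, NRRD, DICOM series). SimpleITK
arrays come back as (z, y, x); they are transposed to (x, y, z) on read and
back on write so that ``vol.voxels[i, j, k]`` addresses voxel (i, j, k) of
an annotation.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .tissue import KERNELS, TissueClass

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("scan_id", "subject_id", "i", "j", "k", "label", "kernel")


class VolumeFormatError(ValueError):
    """File could not be parsed as the named raster format."""


class VolumeMetadataError(ValueError):
    """Required geometric metadata (spacing) missing or inconsistent."""


class AnnotationError(ValueError):
    """Annotation table malformed or labels invalid."""


@dataclass
class CTVolume:
    """A CT scan in Hounsfield units with voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation in HU.
    spacing : tuple of float
        Voxel size (x, y, z) in mm; strictly positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    lung_mask : ndarray or None
        Binary mask, nonzero = lung, same shape as ``voxels``.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    lung_mask: Optional[np.ndarray] = None
    scan_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeMetadataError(
                f"spacing must be 3 strictly positive values, got {self.spacing}"
            )
        self.origin = tuple(float(o) for o in self.origin)
        if self.lung_mask is not None:
            self.lung_mask = np.asarray(self.lung_mask)
            if self.lung_mask.shape != self.voxels.shape:
                raise ValueError(
                    f"lung_mask shape {self.lung_mask.shape} != "
                    f"voxels shape {self.voxels.shape}"
                )

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def lung_volume_ml(self) -> Optional[float]:
        """Total lung volume from the mask in mL, or None without a mask."""
        if self.lung_mask is None:
            return None
        return float(np.count_nonzero(self.lung_mask)) * self.voxel_volume_ml()


@dataclass(frozen=True)
class AnnotatedPoint:
    """One expert-labelled lung location.

    ``coord`` is a 0-based (i, j, k) voxel index into the scan named by
    ``scan_id``; ``kernel`` tags the reconstruction filter of the image the
    point was placed on (B35 soft / B50 sharp).
    """

    scan_id: str
    coord: tuple
    label: TissueClass
    kernel: str = "B50"
    subject_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "coord", tuple(int(c) for c in self.coord))
        if len(self.coord) != 3:
            raise ValueError(f"coord must have 3 components, got {self.coord}")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if not isinstance(self.label, TissueClass):
            object.__setattr__(self, "label", TissueClass.from_name(str(self.label)))


def _detect_format(path: str) -> str:
    p = Path(path)
    if p.is_dir():
        return "dicom_dir"
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise VolumeFormatError(f"cannot infer volume format from {path!r}")


def read_volume(path, format: Optional[str] = None,
                mask_path=None, scan_id: Optional[str] = None) -> CTVolume:
    """Read a CT volume (NIfTI, NRRD or DICOM series directory).

    Parameters
    ----------
    path : str or Path
        File, or directory containing exactly one DICOM series.
    format : {"nifti", "nrrd", "dicom_dir"} or None
        Inferred from the path when None.
    mask_path : optional
        Raster of the same geometry read as the lung mask (nonzero = lung).

    Returns
    -------
    CTVolume
        Voxels in HU, axis order (x, y, z), spacing from the header.
    """
    path = str(path)
    fmt = format or _detect_format(path)
    if fmt in ("nifti", "nrrd"):
        if not os.path.isfile(path):
            raise VolumeFormatError(f"no such file: {path}")
        try:
            img = sitk.ReadImage(path)
        except Exception as e:  # SimpleITK raises RuntimeError
            raise VolumeFormatError(f"could not read {path} as {fmt}: {e}") from e
    elif fmt == "dicom_dir":
        if not os.path.isdir(path):
            raise VolumeFormatError(f"no such directory: {path}")
        img = _read_dicom_series(path)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")

    voxels = sitk.GetArrayFromImage(img)  # (z, y, x)
    if voxels.ndim != 3:
        raise VolumeMetadataError(f"expected a 3D volume, got ndim={voxels.ndim}")
    voxels = np.ascontiguousarray(voxels.transpose(2, 1, 0))
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    mask = None
    if mask_path is not None:
        mvol = read_volume(mask_path)
        if mvol.shape != voxels.shape:
            raise VolumeMetadataError(
                f"mask shape {mvol.shape} != volume shape {voxels.shape}"
            )
        mask = mvol.voxels != 0
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin,
                    lung_mask=mask, scan_id=scan_id or Path(path).stem.split(".")[0])


def _read_dicom_series(directory: str) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    ids = reader.GetGDCMSeriesIDs(directory)
    if not ids:
        raise VolumeFormatError(f"no DICOM series found in {directory}")
    files = reader.GetGDCMSeriesFileNames(directory, ids[0])
    reader.SetFileNames(files)
    try:
        img = reader.Execute()
    except Exception as e:
        raise VolumeFormatError(f"could not read DICOM series: {e}") from e
    _check_uniform_slice_spacing(files)
    return img

def _check_uniform_slice_spacing(files: Sequence[str], tol: float = 1e-3) -> None:
    import pydicom

    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise VolumeMetadataError(f"slice {f} missing ImagePositionPatient")
        zs.append(float(ipp[2]))
    zs = np.sort(np.asarray(zs))
    if len(zs) > 2:
        gaps = np.diff(zs)
        if np.ptp(gaps) > tol:
            raise VolumeMetadataError(
                f"non-uniform DICOM slice spacing: gaps range "
                f"[{gaps.min():.4f}, {gaps.max():.4f}] mm"
            )


def write_volume(vol: CTVolume, path) -> None:
    """Write a volume to NIfTI or NRRD (by extension), preserving geometry."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def write_mask(vol: CTVolume, path) -> None:
    if vol.lung_mask is None:
        raise ValueError("volume has no lung mask")
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.lung_mask.astype(np.uint8).transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_annotations(path) -> list:
    """Read annotated points from delimited text (CSV or TSV).

    The header must contain scan_id, subject_id, i, j, k, label, kernel.
    Unknown labels raise :class:`AnnotationError` naming the offending rows;
    an empty table yields an empty list with a warning.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"scan_id": str, "subject_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation file missing columns {sorted(missing)}")
    if len(df) == 0:
        warnings.warn(f"annotation file {path} contains no points")
        logger.warning("annotation file %s contains no points", path)
        return []
    valid = {c.name for c in TissueClass}
    bad = df.loc[~df["label"].astype(str).str.strip().str.upper().isin(valid)]
    if len(bad):
        rows = ", ".join(f"row {r}: {v!r}" for r, v in
                         zip(bad.index.tolist()[:10], bad["label"].tolist()[:10]))
        raise AnnotationError(f"unknown tissue labels ({rows})")
    return [
        AnnotatedPoint(
            scan_id=str(r.scan_id), subject_id=str(r.subject_id),
            coord=(int(r.i), int(r.j), int(r.k)),
            label=TissueClass.from_name(str(r.label)), kernel=str(r.kernel),
        )
        for r in df.itertuples()
    ]


def write_annotations(points, path) -> None:
    df = pd.DataFrame(
        [
            {"scan_id": p.scan_id, "subject_id": p.subject_id,
             "i": p.coord[0], "j": p.coord[1], "k": p.coord[2],
             "label": p.label.name, "kernel": p.kernel}
            for p in points
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def check_bounds(points, vol: CTVolume, margin=(24, 24, 24)) -> list:
    """Return the points whose coordinate is out of bounds given a margin.

    Out-of-bounds points are reported, not silently dropped: the caller
    decides whether reflect padding makes them usable.
    """
    shape = vol.shape
    out = []
    for p in points:
        if any(c - m < 0 or c + m > s for c, m, s in zip(p.coord, margin, shape)):
            out.append(p)
    return out
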