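"""Canonical CT image model, HU conventions, geometry, and mask arithmetic.

Coordinate convention
---------------------
In-plane positions are given in millimetres from the grid corner, with the
centre of pixel ``(row i, col j)`` at ``((i + 0.5) * dy, (j + 0.5) * dx)``.
Arrays are indexed ``(slice, row, col)`` for volumes and ``(row, col)`` for
single slices; in-plane pixels must be square.

HU convention
-------------
Hounsfield units with air at -1024. Images are clamped to the 12-bit window
``[-1024, 3071]`` before any normalisation (the 0-4095 offset scale used by
the network is ``HU + 1024``).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Allowed provenance tags for a CT image.
DOMAIN_TAGS = ("planning", "dect", "pseudo_dect", "vnc")

#: Geometry tolerance (mm) for the pixel-count x spacing == FOV invariant.
FOV_TOL_MM = 0.5


class GeometryError(ValueError):
    """Raised when image geometry metadata is absent or inconsistent."""


@dataclass
class CTImage:
    """A 2D slice or 3D stack of CT numbers on a regular grid.

    Parameters
    ----------
    voxels : ndarray
        HU values, shape ``(ny, nx)`` or ``(nz, ny, nx)``.
    spacing_mm : tuple of float
        Per-axis pixel size, same length as ``voxels.ndim``; the two
        in-plane entries must be equal (square pixels).
    domain_tag : str
        Provenance: ``planning``, ``dect``, ``pseudo_dect`` or ``vnc``.
    fov_mm : float, optional
        In-plane field-of-view diameter. Defaults to ``nx * dx``.
    origin_mm : tuple of float, optional
        Position of the grid corner; defaults to zeros.
    slice_index : int, optional
        Index of this slice within a parent volume.
    """

    voxels: np.ndarray
    spacing_mm: tuple
    domain_tag: str = "planning"
    fov_mm: float | None = None
    origin_mm: tuple | None = None
    slice_index: int | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim not in (2, 3):
            raise GeometryError(f"voxels must be 2D or 3D, got ndim={self.voxels.ndim}")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing_mm))
        if len(spacing) == 1:
            spacing = spacing * self.voxels.ndim
        if len(spacing) != self.voxels.ndim:
            raise GeometryError(
                f"spacing_mm has {len(spacing)} entries for a {self.voxels.ndim}D image"
            )
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing_mm must be strictly positive, got {spacing}")
        if abs(spacing[-1] - spacing[-2]) > 1e-6:
            raise GeometryError(f"in-plane pixels must be square, got {spacing[-2:]}")
        self.spacing_mm = spacing
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"domain_tag must be one of {DOMAIN_TAGS}, got {self.domain_tag!r}")
        if self.fov_mm is None:
            self.fov_mm = self.voxels.shape[-1] * spacing[-1]
        self.fov_mm = float(self.fov_mm)
        if abs(self.voxels.shape[-1] * spacing[-1] - self.fov_mm) > FOV_TOL_MM:
            raise GeometryError(
                f"in-plane pixel count x spacing = {self.voxels.shape[-1] * spacing[-1]:.3f} mm "
                f"differs from fov_mm = {self.fov_mm:.3f} by more than {FOV_TOL_MM} mm"
            )
        if self.origin_mm is None:
            self.origin_mm = (0.0,) * self.voxels.ndim
        else:
            self.origin_mm = tuple(float(v) for v in self.origin_mm)

    # -- basic geometry -------------------------------------------------

    @property
    def ndim(self) -> int:
        return self.voxels.ndim

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def inplane_spacing(self) -> float:
        return self.spacing_mm[-1]

    @property
    def n_slices(self) -> int:
        return 1 if self.voxels.ndim == 2 else self.voxels.shape[0]

    def slices(self):
        """Iterate over 2D slice arrays (a 2D image yields itself once)."""
        if self.voxels.ndim == 2:
            yield self.voxels
        else:
            yield from self.voxels

    def get_slice(self, k: int) -> np.ndarray:
        if self.voxels.ndim == 2:
            if k != 0:
                raise IndexError(f"2D image has a single slice, asked for {k}")
            return self.voxels
        return self.voxels[k]

    def with_voxels(self, voxels: np.ndarray, domain_tag: str | None = None) -> "CTImage":
        """Copy of this image carrying new voxels (same geometry)."""
        img = replace(self, voxels=np.asarray(voxels, dtype=np.float32))
        if domain_tag is not None:
            img.domain_tag = domain_tag
        return img

    def pixel_centers_mm(self):
        """In-plane pixel-centre coordinates ``(y_mm[ny], x_mm[nx])``."""
        ny, nx = self.voxels.shape[-2:]
        dy, dx = self.spacing_mm[-2], self.spacing_mm[-1]
        return (np.arange(ny) + 0.5) * dy, (np.arange(nx) + 0.5) * dx


def clamp_hu(values: np.ndarray) -> np.ndarray:
    """Clamp HU values to the 12-bit window [-1024, 3071]."""
    return np.clip(values, HU_MIN, HU_MAX)


def round_hu(values: np.ndarray) -> np.ndarray:
    """Round HU to integers, half away from zero (export quantisation)."""
    v = np.asarray(values, dtype=np.float64)
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


@dataclass
class BodyMask:
    """Binary grid marking the patient interior, congruent with a CTImage."""

    mask: np.ndarray
    component_count: int = 1
    filled: bool = True

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple:
        """(row, col) centroid of the foreground, in pixel units."""
        idx = np.argwhere(self.mask if self.mask.ndim == 2 else self.mask.any(axis=0))
        if idx.size == 0:
            raise ValueError("empty body mask has no centroid")
        return tuple(idx.mean(axis=0))


@dataclass
class ROISpec:
    """A circular in-plane ROI repeated over consecutive slices.

    ``center_mm`` is ``(x, y)`` in the in-plane coordinate convention above;
    ``slice_range`` lists the slice indices the ROI covers (default: a single
    slice 0; phantom analysis conventionally uses three consecutive slices).
    """

    center_mm: tuple
    radius_mm: float
    slice_range: tuple = (0,)
    label: str = ""

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        self.slice_range = tuple(int(k) for k in np.atleast_1d(self.slice_range))
        if len(self.slice_range) == 0:
            raise ValueError("slice_range must be non-empty")
        self.center_mm = (float(self.center_mm[0]), float(self.center_mm[1]))


def circle_mask(image: CTImage, roi: ROISpec) -> np.ndarray:
    """2D boolean mask of pixels whose *centre* lies within the ROI circle.

    The inclusion rule is pixel-centre-inside-radius (boundary inclusive).
    """
    cx, cy = roi.center_mm
    y_mm, x_mm = image.pixel_centers_mm()
    if not (0 <= cx <= image.voxels.shape[-1] * image.inplane_spacing
            and 0 <= cy <= image.voxels.shape[-2] * image.spacing_mm[-2]):
        raise ValueError(f"ROI centre {roi.center_mm} lies outside the image")
    dy = y_mm[:, None] - cy
    dx = x_mm[None, :] - cx
    return dy * dy + dx * dx <= roi.radius_mm ** 2


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path) -> str:
    p = Path(path)
    name = p.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if p.is_dir() or name.endswith(".dcm"):
        return "dicom"
    raise ValueError(f"cannot infer image format from {path}")


def read_ct(path, format: str | None = None, domain_tag: str = "planning") -> CTImage:
    """Read a CT image (NIfTI volume or DICOM series) into HU.

    DICOM stored values are rescaled with RescaleSlope/RescaleIntercept; a
    series without rescale tags is taken to hold HU directly (with a
    warning). Missing geometry metadata is a hard error naming the tag.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, domain_tag)
    if fmt == "dicom":
        return _read_dicom(path, domain_tag)
    raise ValueError(f"unsupported format {fmt!r}")


def _read_nifti(path, domain_tag: str) -> CTImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()
    # NIfTI stores (x, y, z); our arrays are (z, y, x).
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim == 2:
        voxels = data.T
        spacing = (float(zooms[1]), float(zooms[0]))
    elif data.ndim == 3:
        voxels = np.transpose(data, (2, 1, 0))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    else:
        raise GeometryError(f"unsupported NIfTI dimensionality {data.ndim}")
    if any(z <= 0 for z in spacing):
        raise GeometryError("NIfTI header pixdim missing or non-positive")
    return CTImage(voxels=voxels, spacing_mm=spacing, domain_tag=domain_tag)


def _read_dicom(path, domain_tag: str) -> CTImage:
    import pydicom

    p = Path(path)
    files = sorted(p.glob("*.dcm")) if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no DICOM files under {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def position_z(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=position_z)
    spacings = set()
    slices = []
    origin = None
    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise GeometryError("DICOM slice is missing PixelSpacing")
        spacings.add((round(float(ds.PixelSpacing[0]), 6), round(float(ds.PixelSpacing[1]), 6)))
        arr = ds.pixel_array.astype(np.float32)
        if "RescaleSlope" in ds and "RescaleIntercept" in ds:
            arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        else:
            warnings.warn("DICOM slice without rescale tags: stored values taken as HU")
        slices.append(arr)
        if origin is None and "ImagePositionPatient" in ds:
            origin = tuple(float(v) for v in ds.ImagePositionPatient)
    if len(spacings) > 1:
        raise GeometryError(f"mixed pixel spacings in series: {sorted(spacings)}")
    dy, dx = spacings.pop()
    if len(slices) == 1:
        voxels = slices[0]
        spacing = (dy, dx)
    else:
        voxels = np.stack(slices)
        dz = 1.0
        if len(datasets) > 1 and "ImagePositionPatient" in datasets[0]:
            dz = abs(position_z(datasets[1]) - position_z(datasets[0])) or 1.0
        spacing = (dz, dy, dx)
    return CTImage(voxels=voxels, spacing_mm=spacing, domain_tag=domain_tag)


def write_ct(image: CTImage, path, format: str | None = None) -> None:
    """Write a CTImage as NIfTI (one volume) or DICOM (one file per slice).

    HU values are quantised to integers (half away from zero) on export, so
    the write/read round trip is lossless up to that quantisation.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(image, path)
    elif fmt == "dicom":
        _write_dicom(image, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def _write_nifti(image: CTImage, path) -> None:
    import nibabel as nib

    voxels = round_hu(image.voxels).astype(np.int16)
    if voxels.ndim == 2:
        data = voxels.T
        dx, dy, dz = image.spacing_mm[1], image.spacing_mm[0], 1.0
    else:
        data = np.transpose(voxels, (2, 1, 0))
        dz, dy, dx = image.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz)[: data.ndim])
    img.header["descrip"] = f"vncct domain={image.domain_tag}".encode()[:79]
    nib.save(img, str(path))


def _write_dicom(image: CTImage, path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    dz = image.spacing_mm[0] if image.ndim == 3 else 1.0
    for k, sl in enumerate(image.slices()):
        stored = round_hu(sl).astype(np.int16)
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
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [f"{image.spacing_mm[-2]:.6f}", f"{image.spacing_mm[-1]:.6f}"]
        ds.ImagePositionPatient = [0.0, 0.0, k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        ds.is_little_endian = True
        ds.is_implicit_VR = False
        pydicom.dcmwrite(str(outdir / f"slice_{k:04d}.dcm"), ds, write_like_original=False)
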