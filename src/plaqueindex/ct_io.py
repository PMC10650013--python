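"""Volumetric CT image and mask I/O with explicit spacing metadata.

Conventions
-----------
Voxel arrays are indexed ``(z, y, x)`` (slice, row, column); ``spacing`` and
``origin`` are stored in world order ``(x, y, z)`` millimetres, matching the
NIfTI / MetaImage header convention. All voxel index ranges are 0-based and
half-open. File readers normalise to this layout, so the rest of the package
never has to reason about axis order.

Supported containers are NIfTI-1 (``.nii``, ``.nii.gz``) and MetaImage
(``.mha``, ``.mhd``); DICOM series are deliberately unsupported — convert to
NIfTI first. Hounsfield units are stored as provided by the file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTIOError",
    "CTVolume",
    "MaskVolume",
    "ROIBox",
    "read_volume",
    "write_volume",
    "crop_to_roi",
]

_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class CTIOError(ValueError):
    """Raised for unreadable files, bad metadata, or invalid geometry."""


def _check_geometry(voxels: np.ndarray, spacing, origin) -> None:
    if voxels.ndim != 3 or voxels.size == 0:
        raise CTIOError(f"voxel array must be 3-D and non-empty, got shape {voxels.shape}")
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise CTIOError(f"spacing must be three positive finite values, got {spacing}")
    if len(origin) != 3 or any(not np.isfinite(o) for o in origin):
        raise CTIOError(f"origin must be three finite values, got {origin}")


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Hounsfield units, integer or float.
    spacing : tuple of float
        Voxel size ``(sx, sy, sz)`` in mm.
    origin : tuple of float
        World position ``(x, y, z)`` in mm of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.voxels, self.spacing, self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise CTIOError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # (nz, ny, nx)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class MaskVolume:
    """A binary mask sharing the geometry of a parent :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise CTIOError(f"mask values must be in {{0,1}}, found {vals[:5]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.voxels, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3


@dataclass(frozen=True)
class ROIBox:
    """Half-open voxel-index box ``[lo, hi)`` in (z, y, x) order."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise CTIOError("ROIBox lo/hi must each have three components")
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise CTIOError(f"ROIBox requires lo < hi componentwise, got lo={self.lo} hi={self.hi}")
        if any(l < 0 for l in self.lo):
            raise CTIOError(f"ROIBox lo must be non-negative, got {self.lo}")


def _check_suffix(path: str | Path) -> None:
    name = str(path)
    if not name.endswith(_SUFFIXES):
        raise CTIOError(f"unsupported volume format for {name!r}; expected one of {_SUFFIXES}")


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage volume, normalised to (z, y, x) axis order.

    Spacing and origin come from the file header; a header without strictly
    positive spacing is rejected rather than silently assumed to be 1 mm.
    """
    path = str(path)
    if not os.path.exists(path):
        raise CTIOError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise CTIOError(f"unreadable volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise CTIOError(f"{path}: expected a 3-D volume, got {img.GetDimension()}-D")
    spacing = tuple(img.GetSpacing())  # (sx, sy, sz)
    if any(s <= 0 for s in spacing):
        raise CTIOError(f"{path}: header spacing {spacing} is not strictly positive")
    voxels = sitk.GetArrayFromImage(img)  # already (z, y, x)
    return CTVolume(voxels=voxels, spacing=spacing, origin=tuple(img.GetOrigin()))


def write_volume(vol: CTVolume | MaskVolume, path: str | Path) -> None:
    """Write a volume or mask; masks are stored as unsigned 8-bit.

    Integer-typed volumes round-trip bit-compatibly through
    :func:`read_volume`.
    """
    path = str(path)
    _check_suffix(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise CTIOError(f"output directory does not exist: {parent}")
    arr = vol.voxels
    if isinstance(vol, MaskVolume):
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    try:
        sitk.WriteImage(img, path)
    except Exception as exc:
        raise CTIOError(f"failed to write {path}: {exc}") from exc


def crop_to_roi(vol: CTVolume, roi: ROIBox) -> CTVolume:
    """Crop to a half-open (z, y, x) index box; origin shifts accordingly."""
    shape = vol.shape
    if any(h > n for h, n in zip(roi.hi, shape)):
        raise CTIOError(f"ROI hi={roi.hi} exceeds volume shape {shape}")
    k0, j0, i0 = roi.lo
    k1, j1, i1 = roi.hi
    sub = vol.voxels[k0:k1, j0:j1, i0:i1].copy()
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    new_origin = (ox + i0 * sx, oy + j0 * sy, oz + k0 * sz)
    return replace(vol, voxels=sub, origin=new_origin)
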