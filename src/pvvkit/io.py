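"""Reading and writing 3D volumes with correct physical-space metadata.

SimpleITK backs the file formats (NIfTI ``.nii``/``.nii.gz``, MetaImage
``.mha``/``.mhd``, NRRD ``.nrrd``); pydicom backs DICOM series reading.
On read, every volume is normalized to the package convention: arrays indexed
``(x, y, z)`` with ``z`` the slice axis (SimpleITK's numpy view is ``(z, y,
x)`` and is transposed).  Round-trips through :func:`write_volume` /
:func:`read_volume` are lossless at the voxel level.

Spacing is never silently assumed: files whose headers carry non-positive
spacing are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

from .grid import VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "write_provenance_sidecar",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


class VolumeFormatError(RuntimeError):
    """Raised for unreadable files or unusable spatial metadata."""


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unrecognized volume format for {path.name!r}; "
            f"supported suffixes: {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a volumetric image file into a :class:`VoxelGrid`.

    The returned grid is indexed ``(x, y, z)`` with spacing taken from the
    file header.  Raises :class:`VolumeFormatError` on unreadable files or
    non-positive spacing — a missing spacing is never replaced by 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{path.name}: expected a 3D volume, got {img.GetDimension()}D"
        )
    spacing = img.GetSpacing()  # (x, y, z) in ITK
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(
            f"{path.name}: non-positive voxel spacing {spacing} in header; "
            "refusing to assume 1 mm"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return VoxelGrid(data=data, spacing=tuple(spacing), origin=tuple(img.GetOrigin()))


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` to NIfTI / MetaImage / NRRD by suffix."""
    path = Path(path)
    _check_suffix(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, str(path))
    return path


def read_dicom_series(directory: str | Path) -> VoxelGrid:
    """Read a single coherent axial DICOM series from a directory.

    Slices are sorted by their position along the slice normal; in-plane
    spacing comes from PixelSpacing and the through-plane spacing from the
    inter-slice distance.  A directory holding more than one series, or
    slices missing position tags, is an error.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM clutter (e.g. DICOMDIR fragments)
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no DICOM image slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise VolumeFormatError(
            f"{directory} contains {len(uids)} series; expected exactly one"
        )
    for ds in slices:
        if not hasattr(ds, "ImagePositionPatient"):
            raise VolumeFormatError("slice missing ImagePositionPatient tag")
        if not hasattr(ds, "PixelSpacing"):
            raise VolumeFormatError("slice missing PixelSpacing tag")

    # Sort along the slice normal (z of ImagePositionPatient for axial data).
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(slices) < 2:
        raise VolumeFormatError("need at least 2 slices to derive slice spacing")
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise VolumeFormatError("duplicate or non-monotonic slice positions")
    if not np.allclose(gaps, gaps[0], rtol=1e-3, atol=1e-3):
        raise VolumeFormatError(
            f"non-uniform slice spacing (gaps {gaps.min():.3f}–{gaps.max():.3f} mm)"
        )
    dz = float(gaps[0])
    # DICOM PixelSpacing is (row spacing, column spacing) = (dy, dx).
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise VolumeFormatError("non-positive spacing in DICOM tags")

    stack = np.stack([ds.pixel_array for ds in slices], axis=0)  # (z, rows, cols)
    data = np.ascontiguousarray(stack.transpose(2, 1, 0))  # (x, y, z)
    first = slices[0]
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    return VoxelGrid(data=data, spacing=(dx, dy, dz), origin=origin)


def write_provenance_sidecar(
    path: str | Path, method: str, parameters: dict
) -> Path:
    """Write a JSON sidecar recording method name, parameters, and version."""
    from . import __version__

    path = Path(path)
    payload = {
        "method": method,
        "parameters": parameters,
        "package": "pvvkit",
        "version": __version__,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
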