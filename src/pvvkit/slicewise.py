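"""The "unfiltered" slice-wise PVV estimator.

Each image plane is treated independently: 2D connected components of the
vessel-like mask are measured by cross-sectional area (pixel count times
in-plane pixel area) and each component contributes ``area x slice
thickness`` of volume to the sub-volume bin its area falls in.  No 3D
connectivity, denoising, or orientation correction is applied — deliberately.
This is the estimator used by prior PVV studies, and it carries two known
artifacts that the graph-based method is designed to remove: the
cross-sectional area of a vessel oblique to the image plane is inflated by
~1/cos(theta), and small unconnected clutter (e.g. reticular pattern
misclassified as vessel) is counted in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .result import DEFAULT_AREA_THRESHOLDS, PVVResult, area_bin

__all__ = ["SliceComponent", "label_slice_components", "slicewise_pvv"]

# 8-connectivity within a slice: avoids fragmenting thin oblique vessels
_STRUCTURE_2D = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SliceComponent:
    """One 2D connected component on one image plane."""

    slice_index: int
    voxel_count: int
    area: float  # mm^2


def label_slice_components(mask: VoxelGrid, slice_index: int) -> list[SliceComponent]:
    """2D 8-connected components of one slice with areas in mm^2."""
    data = mask.as_bool()
    if not 0 <= slice_index < data.shape[2]:
        raise IndexError(
            f"slice_index {slice_index} outside volume with {data.shape[2]} slices"
        )
    plane = data[:, :, slice_index]
    labels, n = ndimage.label(plane, structure=_STRUCTURE_2D)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    pixel_area = mask.pixel_area
    return [
        SliceComponent(slice_index=slice_index, voxel_count=int(c),
                       area=float(c) * pixel_area)
        for c in counts
    ]


def slicewise_pvv(
    mask: VoxelGrid,
    area_thresholds: tuple[float, float] = DEFAULT_AREA_THRESHOLDS,
    slice_multiplier: float | None = None,
) -> PVVResult:
    """Slice-wise ("unfiltered") PVV with its PVV5/PVV10/PVV10+ partition.

    Parameters
    ----------
    mask : binary VoxelGrid
        Vessel-like mask on an (x, y, z) grid with z the slice axis.
    area_thresholds : (lo, hi) in mm^2
        Bin edges of the sub-volume partition, default (5, 10).
    slice_multiplier : float, optional
        Volume multiplier per unit area, in mm.  Defaults to the slice
        thickness (dz) from the grid metadata; pass the slice spacing
        explicitly to use it instead when slices overlap.
    """
    lo, hi = area_thresholds
    if not lo < hi:
        raise ValueError(f"area thresholds must be strictly increasing, got {area_thresholds}")
    if slice_multiplier is None:
        slice_multiplier = mask.slice_thickness
    if slice_multiplier <= 0:
        raise ValueError("slice multiplier must be > 0")

    data = mask.as_bool()
    pixel_area = mask.pixel_area
    bins = {"pvv5": 0.0, "pvv10": 0.0, "pvv10plus": 0.0}
    for k in range(data.shape[2]):
        plane = data[:, :, k]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane, structure=_STRUCTURE_2D)
        counts = np.bincount(labels.ravel())[1:]
        areas = counts.astype(float) * pixel_area
        volumes = areas * slice_multiplier  # mm^3
        for area, vol in zip(areas, volumes):
            bins[area_bin(float(area), area_thresholds)] += float(vol)

    return PVVResult(
        method="unfiltered",
        pvv5=bins["pvv5"] / 1000.0,
        pvv10=bins["pvv10"] / 1000.0,
        pvv10plus=bins["pvv10plus"] / 1000.0,
        parameters={
            "area_thresholds_mm2": list(area_thresholds),
            "slice_multiplier_mm": float(slice_multiplier),
            "connectivity_2d": 8,
        },
    )
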