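"""Derived ROIs: largest axial cross-section and the two circular ROIs.

A 3D lesion segmentation yields a 2D ROI (the axial slice with the largest
foreground area) and, for simplified-protocol comparisons, two circles on
that slice: the minimum circle enclosing the lesion cross-section and the
maximum circle inscribed in it.  All circle computations are done in
physical millimetres using the in-plane spacing; a voxel belongs to a circle
iff its centre lies at distance <= radius (centre-inclusion rasterisation).
"""

from __future__ import annotations

import numpy as np
import shapely

from .errors import DomainError
from .volume import RoiMask

_EPS = 1e-9


def largest_axial_cross_section(mask: RoiMask) -> RoiMask:
    """Single axial slice of a 3D mask with maximal foreground area (mm^2).

    Ties are broken by the lowest z index.
    """
    if mask.is_empty():
        raise DomainError("cannot take a cross-section of an empty mask")
    areas = mask.values.sum(axis=(0, 1))          # per-slice voxel counts
    z = int(np.argmax(areas))                     # first maximum = lowest z
    out = np.zeros_like(mask.values)
    out[:, :, z] = mask.values[:, :, z]
    return mask.with_values(out, dimensionality="2D-axial", shape_tag="manual")


def _slice_points_mm(mask2d: RoiMask) -> tuple[np.ndarray, int]:
    """Foreground voxel centres of a 2D-axial mask as (N, 2) mm coordinates."""
    if mask2d.is_empty():
        raise DomainError("empty 2D mask")
    z = mask2d.axial_slice_index
    sx, sy, _ = mask2d.spacing
    ij = np.argwhere(mask2d.values[:, :, z])
    return ij * np.array([sx, sy]), z


def _rasterize_circle(mask2d: RoiMask, center_mm: np.ndarray, radius_mm: float,
                      z: int, shape_tag: str) -> RoiMask:
    sx, sy, _ = mask2d.spacing
    nx, ny = mask2d.shape[:2]
    xs = np.arange(nx) * sx - center_mm[0]
    ys = np.arange(ny) * sy - center_mm[1]
    inside = (xs[:, None] ** 2 + ys[None, :] ** 2) <= (radius_mm + _EPS) ** 2
    out = np.zeros(mask2d.shape, dtype=bool)
    out[:, :, z] = inside
    return mask2d.with_values(out, dimensionality="2D-axial", shape_tag=shape_tag)


def min_enclosing_circle_roi(mask2d: RoiMask) -> RoiMask:
    """Rasterised minimum enclosing circle of a 2D ROI's voxel centres.

    The circle is computed in mm over the foreground voxel centres; the
    output is a superset of the input foreground.
    """
    pts, z = _slice_points_mm(mask2d)
    if len(pts) == 1:
        center, radius = pts[0], 0.0
    else:
        geom = shapely.MultiPoint(pts)
        radius = float(shapely.minimum_bounding_radius(geom))
        circle = shapely.minimum_bounding_circle(geom)
        center = np.asarray(circle.centroid.coords[0])
    return _rasterize_circle(mask2d, np.asarray(center, dtype=float), radius, z,
                             "circle_enclosing")


def _distance_to_background_mm(fg_pts: np.ndarray, bg_pts: np.ndarray,
                               half: np.ndarray) -> np.ndarray:
    """Exact distance from foreground voxel centres to the background region.

    The background region is the union of background voxel rectangles of
    half-extents ``half = (sx/2, sy/2)``; distance from a point to a
    rectangle is ``hypot(max(|dx|-hx, 0), max(|dy|-hy, 0))``.
    """
    best = np.full(len(fg_pts), np.inf)
    # chunk over foreground to bound the (F, B) temporary
    chunk = max(1, int(4e6 / max(len(bg_pts), 1)))
    for start in range(0, len(fg_pts), chunk):
        f = fg_pts[start:start + chunk]
        d = f[:, None, :] - bg_pts[None, :, :]
        np.abs(d, out=d)
        d -= half
        np.clip(d, 0.0, None, out=d)
        best[start:start + chunk] = np.sqrt((d * d).sum(axis=2)).min(axis=1)
    return best


def max_inscribed_circle_roi(mask2d: RoiMask) -> RoiMask:
    """Rasterised maximum inscribed circle of a 2D ROI.

    The centre is the foreground voxel whose centre maximises the Euclidean
    distance (mm) to the background region (ties broken by lexicographic
    voxel index); the radius is that distance.  The output is a subset of the
    input foreground.
    """
    if mask2d.is_empty():
        raise DomainError("empty 2D mask")
    z = mask2d.axial_slice_index
    sx, sy, _ = mask2d.spacing
    plane = mask2d.values[:, :, z]
    # pad with a background ring so the outside of the grid counts as background
    padded = np.pad(plane, 1, constant_values=False)
    fg_idx = np.argwhere(padded)
    # background voxels 8-adjacent to foreground suffice: the nearest
    # background rectangle to any interior point is adjacent to the mask
    from scipy import ndimage
    ring = ndimage.binary_dilation(padded, structure=np.ones((3, 3), bool)) & ~padded
    bg_idx = np.argwhere(ring)
    scale = np.array([sx, sy])
    half = scale / 2.0
    dist = _distance_to_background_mm(fg_idx * scale, bg_idx * scale, half)
    best = int(np.argmax(dist))                  # first max = lexicographic tie-break
    center_mm = (fg_idx[best] - 1) * scale       # undo padding offset
    radius = float(dist[best])
    return _rasterize_circle(mask2d, center_mm, radius, z, "circle_inscribed")
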