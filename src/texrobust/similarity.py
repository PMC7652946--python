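"""Inter-reader contour agreement: Dice coefficient and average Hausdorff distance.

Dice measures voxel-labelling overlap (0 = disjoint, 1 = identical); the
average Hausdorff distance is the symmetric mean nearest-boundary distance
in mm between the two contours' surfaces and is more sensitive to shape
deviations (spikes, holes) that barely change the overlap.

Boundaries are voxel-centre point sets: foreground voxels with at least one
face-adjacent background neighbour (6-connectivity in 3D, 4-connectivity
in-plane for 2D-axial masks; grid borders count as background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DomainError, PairingError
from .roi import largest_axial_cross_section
from .volume import RoiMask


@dataclass(frozen=True)
class SimilarityResult:
    dice: float
    avg_hausdorff: float        # mm
    lesion_id: str = ""
    roi_mode: str = "3D"


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); symmetric in its arguments."""
    a.check_same_grid(b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise DomainError("Dice is undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def boundary_points_mm(mask: RoiMask) -> np.ndarray:
    """(N, d) mm coordinates of the boundary voxel centres of a mask.

    3D masks use 6-connectivity and return 3D points; 2D-axial masks use
    4-connectivity within the slice and return in-plane 2D points.
    """
    if mask.is_empty():
        raise DomainError("empty mask has no boundary")
    if mask.dimensionality == "2D-axial":
        z = mask.axial_slice_index
        plane = mask.values[:, :, z]
        structure = ndimage.generate_binary_structure(2, 1)
        eroded = ndimage.binary_erosion(plane, structure=structure)
        surface = plane & ~eroded
        sx, sy, _ = mask.spacing
        return np.argwhere(surface) * np.array([sx, sy])
    eroded = ndimage.binary_erosion(mask.values)   # 6-connected, border=0
    surface = mask.values & ~eroded
    return np.argwhere(surface) * np.asarray(mask.spacing)


def average_hausdorff(a: RoiMask, b: RoiMask,
                      spacing: Sequence[float] | None = None) -> float:
    """Symmetric average surface distance between two masks' boundaries (mm).

    ``[sum_{p in dA} min_q d(p,q) + sum_{q in dB} min_p d(p,q)] /
    (|dA| + |dB|)`` over boundary voxel centres; symmetric in its arguments.
    """
    a.check_same_grid(b)
    if spacing is not None and not np.allclose(spacing, a.spacing):
        raise DomainError("explicit spacing disagrees with the masks' spacing")
    pa = boundary_points_mm(a)
    pb = boundary_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


def _as_mode(mask: RoiMask, mode: str) -> RoiMask:
    if mode == "3D":
        return mask
    if mode == "2D":
        if mask.dimensionality == "2D-axial":
            return mask
        return largest_axial_cross_section(mask)
    raise DomainError(f"mode must be '3D' or '2D', got {mode!r}")


def _overlay_2d(a: RoiMask, b: RoiMask) -> tuple[RoiMask, RoiMask]:
    """Overlay two single-slice masks in-plane.

    The two readers may have picked different axial slices as "largest"; 2D
    agreement compares the two cross-sections in the axial plane, so both
    slices are moved to a common z index before comparison.
    """
    za, zb = a.axial_slice_index, b.axial_slice_index
    if za == zb:
        return a, b
    vb = np.zeros_like(b.values)
    vb[:, :, za] = b.values[:, :, zb]
    return a, b.with_values(vb)


def similarity_pair(a: RoiMask, b: RoiMask, mode: str = "3D",
                    lesion_id: str = "") -> SimilarityResult:
    """Dice and average Hausdorff for one reader pair in the given mode."""
    ma, mb = _as_mode(a, mode), _as_mode(b, mode)
    if mode == "2D":
        ma, mb = _overlay_2d(ma, mb)
    return SimilarityResult(dice=dice(ma, mb),
                            avg_hausdorff=average_hausdorff(ma, mb),
                            lesion_id=lesion_id, roi_mode=mode)


def cohort_similarity(
    reader1: Sequence[RoiMask],
    reader2: Sequence[RoiMask],
    mode: str = "3D",
    lesion_ids: Sequence[str] | None = None,
) -> tuple[list[SimilarityResult], dict]:
    """Per-lesion similarity plus cohort median and IQR summaries.

    Quartiles use linear interpolation (numpy's default percentile rule).
    """
    if len(reader1) != len(reader2):
        raise PairingError(
            f"reader lists differ in length: {len(reader1)} vs {len(reader2)}"
        )
    if lesion_ids is None:
        lesion_ids = [f"lesion{i:03d}" for i in range(len(reader1))]
    results = [
        similarity_pair(a, b, mode=mode, lesion_id=lid)
        for a, b, lid in zip(reader1, reader2, lesion_ids)
    ]
    dcs = np.array([r.dice for r in results])
    hds = np.array([r.avg_hausdorff for r in results])
    summary = {
        "mode": mode,
        "n": len(results),
        "dice_median": float(np.median(dcs)),
        "dice_iqr": [float(np.percentile(dcs, 25)), float(np.percentile(dcs, 75))],
        "hausdorff_median_mm": float(np.median(hds)),
        "hausdorff_iqr_mm": [float(np.percentile(hds, 25)),
                             float(np.percentile(hds, 75))],
    }
    return results, summary
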