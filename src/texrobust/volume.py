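"""In-memory containers for CT intensity volumes and binary ROI labelmaps.

Conventions
-----------
* Arrays are indexed ``[x, y, z]``; the last axis is the axial (slice)
  direction, matching the usual NIfTI on-disk layout.
* ``spacing`` is ``(sx, sy, sz)`` in millimetres; physical coordinates are
  voxel-centre based, so voxel ``(i, j, k)`` sits at
  ``origin + (i*sx, j*sy, k*sz)``.
* Voxel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, DomainError

#: Hounsfield clamp range applied to every generated or ingested volume.
HU_MIN_PHYSICAL = -1024.0
HU_MAX_PHYSICAL = 3071.0


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar grid of Hounsfield units with physical voxel spacing."""

    values: np.ndarray                 # float array, axes (x, y, z)
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"            # documentation tag; z is axial

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise DomainError(f"volume must be 3D, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise DomainError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class RoiMask:
    """A binary labelmap congruent with a parent :class:`IntensityVolume`.

    ``dimensionality`` is ``"3D"`` for whole-lesion masks or ``"2D-axial"``
    when all foreground voxels share a single z index.  ``shape_tag``
    distinguishes manually drawn ROIs from the two derived circular ROIs.
    """

    values: np.ndarray                 # bool array, axes (x, y, z)
    spacing: tuple[float, float, float]
    dimensionality: str = "3D"         # {"3D", "2D-axial"}
    shape_tag: str = "manual"          # {"manual", "circle_enclosing", "circle_inscribed"}
    reader_id: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise DomainError(f"mask must be a 3D grid, got ndim={values.ndim}")
        if values.dtype != bool:
            values = values != 0
        if any(s <= 0 for s in self.spacing):
            raise DomainError(f"spacing must be positive, got {self.spacing}")
        if self.dimensionality not in ("3D", "2D-axial"):
            raise DomainError(f"unknown dimensionality {self.dimensionality!r}")
        if self.dimensionality == "2D-axial" and values.any():
            zs = np.unique(np.nonzero(values)[2])
            if zs.size > 1:
                raise DomainError(
                    f"2D-axial mask spans {zs.size} slices; expected exactly one"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()

    @property
    def axial_slice_index(self) -> int:
        """z index of the single slice of a 2D-axial mask."""
        if self.dimensionality != "2D-axial":
            raise DomainError("axial_slice_index is only defined for 2D-axial masks")
        if self.is_empty():
            raise DomainError("empty mask has no slice index")
        return int(np.nonzero(self.values)[2][0])

    def with_values(self, values: np.ndarray, **kwargs) -> "RoiMask":
        """Copy of this mask with new voxel values (and optional field overrides)."""
        base = replace(self, values=values)
        return replace(base, **kwargs) if kwargs else base

    def check_same_grid(self, other: "RoiMask | IntensityVolume") -> None:
        """Raise :class:`AlignmentError` unless grids and spacings match."""
        if self.shape != other.shape:
            raise AlignmentError(
                f"grid shape mismatch: {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.spacing, other.spacing, rtol=1e-6, atol=1e-6):
            raise AlignmentError(
                f"spacing mismatch: {self.spacing} vs {other.spacing}"
            )


def voxel_centers_mm(mask_values: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(N, 3) physical coordinates (mm) of the foreground voxel centres."""
    idx = np.argwhere(mask_values)
    return idx * np.asarray(spacing, dtype=float) + np.asarray(origin, dtype=float)
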