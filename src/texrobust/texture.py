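"""Grey-level discretization and GLCM/GLRLM matrix construction.

Intensities are discretized over a fixed HU window (default 480 grey levels,
-200 to 279 HU, in 32 uniform 15-HU bins).  Co-occurrence and run-length
matrices are accumulated over all unique voxel-offset directions at offset 1
(13 in 3D, 4 in-plane in 2D), with symmetric pair counting; per-direction
matrices are summed into a single matrix before normalisation and feature
computation.  Direction vectors are in voxel steps, not mm: the images are
used at their native anisotropic spacing with no resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMatrixError, DomainError
from .volume import IntensityVolume, RoiMask

# Unique offset-1 directions up to sign: 13 in 3D, 4 in the axial plane.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and ((dx > 0) or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0))
)
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in DIRECTIONS_3D if d[2] == 0
)
assert len(DIRECTIONS_3D) == 13 and len(DIRECTIONS_2D) == 4


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-range grey-level discretization settings.

    The default window spans 480 integer grey levels (-200..279 HU) split
    into 32 uniform bins of 15 HU; ``offset`` is the co-occurrence step in
    voxels and ``symmetric`` toggles counting both orderings of each pair.
    """

    hu_min: float = -200.0
    hu_max: float = 279.0
    n_bins: int = 32
    offset: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.hu_max <= self.hu_min:
            raise DomainError("hu_max must exceed hu_min")
        if self.n_bins < 2:
            raise DomainError("n_bins must be >= 2")
        n_levels = self.hu_max - self.hu_min + 1
        if abs(n_levels / self.n_bins - round(n_levels / self.n_bins)) > 1e-9:
            raise DomainError(
                f"{n_levels:g} grey levels do not divide into {self.n_bins} "
                "uniform bins"
            )
        if self.offset < 1:
            raise DomainError("offset must be >= 1")

    @property
    def n_grey_levels(self) -> float:
        return self.hu_max - self.hu_min + 1

    @property
    def bin_width(self) -> float:
        return self.n_grey_levels / self.n_bins


@dataclass
class DiscretizedROI:
    """Per-voxel bin labels (1..n_bins on foreground, 0 elsewhere)."""

    bin_labels: np.ndarray
    mask: RoiMask
    config: DiscretizationConfig
    n_clamped: int = 0

    @property
    def n_foreground(self) -> int:
        return int((self.bin_labels > 0).sum())


@dataclass
class TextureMatrices:
    """Direction-summed co-occurrence and run-length matrices for one ROI."""

    glcm: np.ndarray | None          # (Ng, Ng) probabilities, sums to 1
    glrlm: np.ndarray | None         # (Ng, Nr) run counts
    directions_used: tuple[tuple[int, int, int], ...]
    mode: str                        # {"3D", "2D"}
    n_foreground: int = 0
    n_bins: int = 0

    @property
    def n_directions(self) -> int:
        return len(self.directions_used)


def _directions_for(mode: str) -> tuple[tuple[int, int, int], ...]:
    if mode == "3D":
        return DIRECTIONS_3D
    if mode == "2D":
        return DIRECTIONS_2D
    raise DomainError(f"mode must be '3D' or '2D', got {mode!r}")


def discretize(volume: IntensityVolume, mask: RoiMask,
               config: DiscretizationConfig | None = None) -> DiscretizedROI:
    """Map foreground HU values to bin labels 1..n_bins.

    ``label = floor((clamp(HU) - hu_min) / bin_width) + 1`` with HU values
    outside ``[hu_min, hu_max]`` clamped to the window (the clamp count is
    recorded) and ``HU == hu_max`` mapped to the last bin.
    """
    config = config or DiscretizationConfig()
    if mask.is_empty():
        raise DomainError("cannot discretize an empty ROI")
    mask.check_same_grid(volume)

    fg = mask.values
    hu = volume.values[fg]
    n_clamped = int(((hu < config.hu_min) | (hu > config.hu_max)).sum())
    if n_clamped == hu.size:
        warnings.warn(
            "all foreground voxels fall outside the discretization window; "
            "texture will be degenerate",
            stacklevel=2,
        )
    clamped = np.clip(hu, config.hu_min, config.hu_max)
    labels_fg = np.floor((clamped - config.hu_min) / config.bin_width).astype(np.int64) + 1
    np.clip(labels_fg, 1, config.n_bins, out=labels_fg)

    labels = np.zeros(mask.shape, dtype=np.int64)
    labels[fg] = labels_fg
    return DiscretizedROI(bin_labels=labels, mask=mask, config=config,
                          n_clamped=n_clamped)


def _bounding_box(labels: np.ndarray) -> tuple[slice, ...]:
    nz = np.nonzero(labels)
    return tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)


def _pair_slices(shape, d, step):
    """Source/destination slice tuples for a voxel offset ``d * step``."""
    src, dst = [], []
    for n, delta in zip(shape, (c * step for c in d)):
        if delta >= 0:
            src.append(slice(0, n - delta))
            dst.append(slice(delta, n))
        else:
            src.append(slice(-delta, n))
            dst.append(slice(0, n + delta))
    return tuple(src), tuple(dst)


def build_glcm(d: DiscretizedROI, mode: str = "3D",
               directions=None) -> TextureMatrices:
    """Direction-summed symmetric grey-level co-occurrence matrix.

    For each direction, bin pairs of foreground voxels separated by
    ``offset`` voxel steps are counted in both orderings; counts are summed
    over directions and normalised to probabilities.  ``directions``
    overrides the mode's default direction set (for single-direction
    analyses).
    """
    directions = _directions_for(mode) if directions is None else tuple(directions)
    ng = d.config.n_bins
    box = _bounding_box(d.bin_labels)
    labels = d.bin_labels[box]
    counts = np.zeros((ng, ng), dtype=np.int64)
    for direction in directions:
        src, dst = _pair_slices(labels.shape, direction, d.config.offset)
        a = labels[src]
        b = labels[dst]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        pair = (a[ok] - 1) * ng + (b[ok] - 1)
        counts += np.bincount(pair, minlength=ng * ng).reshape(ng, ng)
    if d.config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError(
            "ROI has no co-occurring voxel pairs (single voxel?)"
        )
    glcm = counts / total
    return TextureMatrices(glcm=glcm, glrlm=None, directions_used=directions,
                           mode=mode, n_foreground=d.n_foreground, n_bins=ng)


def build_glrlm(d: DiscretizedROI, mode: str = "3D",
                directions=None) -> TextureMatrices:
    """Direction-summed grey-level run-length matrix.

    Foreground voxels are decomposed, per direction, into maximal runs of
    equal bin label (runs truncate at the mask boundary); run counts
    ``r(grey level, length)`` are summed over directions.
    """
    directions = _directions_for(mode) if directions is None else tuple(directions)
    ng = d.config.n_bins
    box = _bounding_box(d.bin_labels)
    labels = d.bin_labels[box]
    shape = np.array(labels.shape)
    nr_alloc = int(shape.max())
    racc = np.zeros((ng, nr_alloc), dtype=np.int64)

    for direction in directions:
        dvec = np.array(direction)
        # run starts: foreground voxels whose predecessor along the direction
        # is outside the mask or has a different bin
        src, dst = _pair_slices(labels.shape, direction, 1)
        prev_same = np.zeros(labels.shape, dtype=bool)
        prev_same[dst] = (labels[dst] > 0) & (labels[src] == labels[dst]) & (labels[src] > 0)
        starts = (labels > 0) & ~prev_same
        pos = np.argwhere(starts)
        if pos.size == 0:
            continue
        bins = labels[tuple(pos.T)]
        lengths = np.ones(len(pos), dtype=np.int64)
        cur = pos.copy()
        active = np.arange(len(pos))
        while active.size:
            nxt = cur[active] + dvec
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(active), dtype=bool)
            if inb.any():
                sub = nxt[inb]
                vals = labels[tuple(sub.T)]
                cont[inb] = vals == bins[active[inb]]
            keep = active[cont]
            cur[keep] = nxt[cont]
            lengths[keep] += 1
            active = keep
        np.add.at(racc, (bins - 1, lengths - 1), 1)

    last = int(np.nonzero(racc.any(axis=0))[0].max()) if racc.any() else 0
    glrlm = racc[:, : last + 1]
    return TextureMatrices(glcm=None, glrlm=glrlm, directions_used=directions,
                           mode=mode, n_foreground=d.n_foreground, n_bins=ng)


def build_matrices(d: DiscretizedROI, mode: str = "3D") -> TextureMatrices:
    """Both matrices in one :class:`TextureMatrices` bundle."""
    glcm = build_glcm(d, mode)
    glrlm = build_glrlm(d, mode)
    return TextureMatrices(glcm=glcm.glcm, glrlm=glrlm.glrlm,
                           directions_used=glcm.directions_used, mode=mode,
                           n_foreground=d.n_foreground, n_bins=d.config.n_bins)
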