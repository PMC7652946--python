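"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested loops, all-pairs scans,
exhaustive enumeration) and shares no code with the package's vectorised
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def glcm_counts_bruteforce(labels: np.ndarray, directions, symmetric: bool,
                           n_bins: int, offset: int = 1) -> np.ndarray:
    """Co-occurrence counts by explicit enumeration of voxel pairs."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    shape = labels.shape
    for idx in np.ndindex(shape):
        a = labels[idx]
        if a == 0:
            continue
        for d in directions:
            nbr = tuple(i + c * offset for i, c in zip(idx, d))
            if any(j < 0 or j >= n for j, n in zip(nbr, shape)):
                continue
            b = labels[nbr]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1
            if symmetric:
                counts[b - 1, a - 1] += 1
    return counts


def glrlm_counts_bruteforce(labels: np.ndarray, directions,
                            n_bins: int) -> np.ndarray:
    """Run-length counts by walking every maximal run voxel by voxel."""
    shape = labels.shape
    max_len = max(shape)
    counts = np.zeros((n_bins, max_len), dtype=np.int64)
    for d in directions:
        for idx in np.ndindex(shape):
            a = labels[idx]
            if a == 0:
                continue
            prev = tuple(i - c for i, c in zip(idx, d))
            in_prev = all(0 <= j < n for j, n in zip(prev, shape))
            if in_prev and labels[prev] == a:
                continue            # not a run start
            length = 0
            cur = idx
            while (all(0 <= j < n for j, n in zip(cur, shape))
                   and labels[cur] == a):
                length += 1
                cur = tuple(i + c for i, c in zip(cur, d))
            counts[a - 1, length - 1] += 1
    nz = np.nonzero(counts.any(axis=0))[0]
    last = int(nz.max()) if nz.size else 0
    return counts[:, : last + 1]


def boundary_voxels_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent background neighbour."""
    ndim = mask.ndim
    shape = mask.shape
    out = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        boundary = False
        for axis in range(ndim):
            for step in (-1, 1):
                nbr = list(idx)
                nbr[axis] += step
                if not (0 <= nbr[axis] < shape[axis]) or not mask[tuple(nbr)]:
                    boundary = True
        if boundary:
            out.append(idx)
    return np.array(out, dtype=float) if out else np.empty((0, ndim))


def average_hausdorff_bruteforce(mask_a: np.ndarray, mask_b: np.ndarray,
                                 spacing) -> float:
    """Symmetric average nearest-boundary distance via all-pairs scan."""
    spacing = np.asarray(spacing, dtype=float)
    pa = boundary_voxels_bruteforce(mask_a) * spacing
    pb = boundary_voxels_bruteforce(mask_b) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return float((d.min(axis=1).sum() + d.min(axis=0).sum())
                 / (len(pa) + len(pb)))


def _circle_through(p1, p2, p3):
    """Circumcircle of three points, or None if collinear."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.asarray(p1)))


def min_enclosing_circle_bruteforce(points: np.ndarray):
    """Smallest enclosing circle by trying all point pairs and triples."""
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return points[0], 0.0
    eps = 1e-9
    best = None
    for p1, p2 in itertools.combinations(points, 2):
        center = (np.asarray(p1) + np.asarray(p2)) / 2.0
        radius = float(np.linalg.norm(np.asarray(p1) - center))
        if np.all(np.linalg.norm(points - center, axis=1) <= radius + eps):
            if best is None or radius < best[1]:
                best = (center, radius)
    for p1, p2, p3 in itertools.combinations(points, 3):
        circ = _circle_through(p1, p2, p3)
        if circ is None:
            continue
        center, radius = circ
        if np.all(np.linalg.norm(points - center, axis=1) <= radius + eps):
            if best is None or radius < best[1]:
                best = (center, radius)
    return best


def distance_to_background_bruteforce(plane: np.ndarray, spacing2d) -> np.ndarray:
    """For every foreground pixel centre, the exact distance (mm) to the
    background region (union of background pixel rectangles, including the
    outside of the grid), by scanning every background pixel of the padded
    plane."""
    sx, sy = spacing2d
    padded = np.pad(plane, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.full(len(fg), np.inf)
    for k, (i, j) in enumerate(fg):
        for bi, bj in bg:
            dx = max(abs(i - bi) * sx - sx / 2.0, 0.0)
            dy = max(abs(j - bj) * sy - sy / 2.0, 0.0)
            out[k] = min(out[k], np.hypot(dx, dy))
    return fg - 1, out


def icc_2way_anova_bruteforce(y1, y2) -> float:
    """ICC(2,1) via an explicit two-way ANOVA decomposition with loops."""
    y = np.column_stack([y1, y2]).astype(float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
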