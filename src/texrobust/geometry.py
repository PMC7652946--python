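"""Small geometric utilities shared across modules.

All distances are in millimetres; point arrays are ``(N, d)`` voxel-centre
coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist


def max_pairwise_distance(points: np.ndarray) -> float:
    """Diameter of a point set: max Euclidean distance over all pairs.

    Uses the convex hull to prune interior points (the diameter is attained
    on hull vertices); falls back to the direct O(N^2) scan for degenerate
    configurations (coplanar / collinear sets that Qhull rejects).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    candidates = points
    if len(points) > 16:
        try:
            hull = ConvexHull(points)
            candidates = points[hull.vertices]
        except QhullError:
            # degenerate (flat) set: drop to an affine subspace and retry
            centred = points - points.mean(axis=0)
            _, s, vt = np.linalg.svd(centred, full_matrices=False)
            keep = s > 1e-9 * max(s[0], 1.0)
            if keep.sum() >= 2:
                proj = centred @ vt[keep].T
                try:
                    hull = ConvexHull(proj)
                    candidates = points[hull.vertices]
                except QhullError:
                    candidates = points
            else:
                candidates = points
    if len(candidates) > 4000:  # pdist memory guard; hull should prevent this
        candidates = candidates[:: len(candidates) // 4000 + 1]
    return float(pdist(candidates).max())


def fibonacci_sphere(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = 2.0 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class SmoothSphereField:
    """A smooth zero-mean, unit-RMS random scalar field on the unit sphere.

    Built as a superposition of ``n_terms`` random cosine waves
    ``cos(wavenumber * (u . d_k) + phase_k)``; ``wavenumber`` sets the angular
    roughness (larger = finer angular detail).  The field is centred and
    scaled empirically on a fixed 512-point Fibonacci quadrature so
    realisations are comparable across seeds: ``normalize="rms"`` gives unit
    RMS (noise-amplitude semantics), ``normalize="peak"`` unit maximum
    absolute value (deformation-amplitude semantics).
    """

    def __init__(self, rng: np.random.Generator, n_terms: int = 8,
                 wavenumber: float = 3.0, normalize: str = "rms"):
        dirs = rng.normal(size=(n_terms, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self._dirs = dirs
        self._phases = rng.uniform(0.0, 2.0 * np.pi, size=n_terms)
        self._amps = rng.normal(size=n_terms)
        self._wavenumber = float(wavenumber)
        quad = self._raw(fibonacci_sphere(512))
        self._mean = float(quad.mean())
        centred = quad - self._mean
        norm = float(centred.std() if normalize == "rms"
                     else np.abs(centred).max())
        self._scale = 1.0 / norm if norm > 1e-12 else 0.0

    def _raw(self, units: np.ndarray) -> np.ndarray:
        proj = units @ self._dirs.T                      # (N, n_terms)
        return np.cos(self._wavenumber * proj + self._phases) @ self._amps

    def __call__(self, units: np.ndarray) -> np.ndarray:
        """Evaluate at (N, 3) unit vectors; returns (N,) values."""
        if self._scale == 0.0:
            return np.zeros(len(units))
        return (self._raw(units) - self._mean) * self._scale
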