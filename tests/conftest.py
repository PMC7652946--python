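"""Shared fixtures: small deterministic phantoms and one full-size cohort.

The full n = 70 cohort (with per-lesion features in both modes) is expensive,
so it is built once per session and shared by the end-to-end property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import texrobust as tx


def make_sphere_mask(radius_vox: float = 6.0, shape=(20, 20, 20),
                     spacing=(1.0, 1.0, 1.0)) -> tx.RoiMask:
    center = np.array(shape) // 2
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return tx.RoiMask(values=dist2 <= radius_vox**2, spacing=spacing)


def make_plane_mask(plane: np.ndarray, spacing=(1.0, 1.0, 1.0),
                    z: int = 0, n_z: int = 1) -> tx.RoiMask:
    """Wrap a 2D boolean array as a single-slice 2D-axial mask."""
    vals = np.zeros(plane.shape + (n_z,), dtype=bool)
    vals[:, :, z] = plane
    return tx.RoiMask(values=vals, spacing=spacing, dimensionality="2D-axial")


@pytest.fixture(scope="session")
def small_lesion():
    """A 30 mm noise-free-boundary lesion with texture, plus its truth mask."""
    spec = tx.LesionSpec(center=(30, 30, 12), target_diameter=30.0,
                         shape_irregularity=0.1)
    vol, truth = tx.generate_lesion_volume(spec, (61, 61, 25),
                                           tx.DEFAULT_SPACING, seed=7)
    return spec, vol, truth


@pytest.fixture(scope="session")
def cohort70():
    """The default-conditions synthetic cohort: 70 lesions, two readers."""
    return tx.generate_cohort(70, master_seed=20)


@pytest.fixture(scope="session")
def cohort70_similarity(cohort70):
    out = {}
    for mode in ("3D", "2D"):
        res, summary = tx.cohort_similarity(
            cohort70.reader1_masks, cohort70.reader2_masks, mode=mode,
            lesion_ids=cohort70.lesion_ids)
        out[mode] = (res, summary)
    return out


@pytest.fixture(scope="session")
def cohort70_features(cohort70):
    """Per-reader feature vectors for all 70 lesions, 3D and 2D modes."""
    vecs = {"r1_3d": [], "r2_3d": [], "r1_2d": [], "r2_2d": []}
    for i, lid in enumerate(cohort70.lesion_ids):
        vol = cohort70.volumes[i]
        r1, r2 = cohort70.reader1_masks[i], cohort70.reader2_masks[i]
        vecs["r1_3d"].append(tx.extract_features(vol, r1, mode="3D", lesion_id=lid))
        vecs["r2_3d"].append(tx.extract_features(vol, r2, mode="3D", lesion_id=lid))
        c1 = tx.largest_axial_cross_section(r1)
        c2 = tx.largest_axial_cross_section(r2)
        vecs["r1_2d"].append(tx.extract_features(vol, c1, mode="2D", lesion_id=lid))
        vecs["r2_2d"].append(tx.extract_features(vol, c2, mode="2D", lesion_id=lid))
    return vecs
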