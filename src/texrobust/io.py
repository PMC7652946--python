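"""NIfTI input/output for intensity volumes and binary labelmaps.

Volumes and masks travel as ``.nii`` / ``.nii.gz`` scalar images whose affine
encodes the voxel spacing; a JSON manifest maps each lesion to its per-reader
labelmap files so a cohort written to disk can be re-ingested by the pipeline.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AlignmentError, DomainError
from .volume import IntensityVolume, RoiMask


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _spacing_origin(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a NIfTI scalar image as an :class:`IntensityVolume` (HU)."""
    path = Path(path)
    if not path.exists():
        raise DomainError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise DomainError(f"{path}: expected a 3D scalar image, got ndim={data.ndim}")
    spacing, origin = _spacing_origin(img)
    return IntensityVolume(values=data, spacing=spacing, origin=origin)


def write_volume(volume: IntensityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_labelmap(path: str | Path, parent: IntensityVolume,
                  **mask_fields) -> RoiMask:
    """Read a NIfTI binary labelmap aligned with ``parent``.

    Any nonzero voxel is foreground; a labelmap with more than two distinct
    values triggers a warning before the coercion.  A grid-shape or spacing
    mismatch with the parent volume raises :class:`AlignmentError`.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DomainError(f"{path}: expected a 3D labelmap, got ndim={data.ndim}")
    spacing, origin = _spacing_origin(img)
    if data.shape != parent.shape:
        raise AlignmentError(
            f"{path}: labelmap grid {data.shape} does not match volume grid "
            f"{parent.shape}"
        )
    if not np.allclose(spacing, parent.spacing, rtol=1e-4, atol=1e-4):
        raise AlignmentError(
            f"{path}: labelmap spacing {spacing} does not match volume spacing "
            f"{parent.spacing}"
        )
    distinct = np.unique(data)
    if distinct.size > 2:
        warnings.warn(
            f"{path}: labelmap has {distinct.size} distinct values; "
            "coercing nonzero to foreground",
            stacklevel=2,
        )
    return RoiMask(values=data != 0, spacing=parent.spacing,
                   origin=origin, **mask_fields)


def write_labelmap(mask: RoiMask, path: str | Path) -> None:
    """Write a mask as a uint8 {0,1} NIfTI labelmap (lossless round-trip)."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------

def write_cohort(cohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort as NIfTI files plus a JSON manifest.

    Layout: ``<outdir>/<lesion_id>_{volume,truth,R1,R2}.nii.gz`` with
    ``manifest.json`` recording per-lesion files, specs and the master seed.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, lesion_id in enumerate(cohort.lesion_ids):
        files = {
            "volume": f"{lesion_id}_volume.nii.gz",
            "truth": f"{lesion_id}_truth.nii.gz",
            "reader1": f"{lesion_id}_R1.nii.gz",
            "reader2": f"{lesion_id}_R2.nii.gz",
        }
        write_volume(cohort.volumes[i], outdir / files["volume"])
        write_labelmap(cohort.truth_masks[i], outdir / files["truth"])
        write_labelmap(cohort.reader1_masks[i], outdir / files["reader1"])
        write_labelmap(cohort.reader2_masks[i], outdir / files["reader2"])
        spec = cohort.lesion_specs[i]
        entries.append({
            "lesion_id": lesion_id,
            "files": files,
            "spec": {
                "center": list(spec.center),
                "target_diameter": spec.target_diameter,
                "lesion_mean_hu": spec.lesion_mean_hu,
                "background_mean_hu": spec.background_mean_hu,
                "texture_correlation_length": spec.texture_correlation_length,
                "noise_sd": spec.noise_sd,
                "boundary_blur_sigma": spec.boundary_blur_sigma,
                "shape_irregularity": spec.shape_irregularity,
            },
        })
    manifest = {
        "master_seed": cohort.master_seed,
        "spacing": list(cohort.spacing),
        "lesions": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort_manifest(manifest_path: str | Path) -> dict:
    """Load a cohort manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DomainError(f"no such manifest: {manifest_path}")
    return json.loads(manifest_path.read_text())
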