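"""IBSI-style GLCM/GLRLM feature formulas and morphology features.

All 32 texture features operate on the direction-summed matrices built by
:mod:`texrobust.texture`.  Notation for the GLCM block: ``p(i, j)`` is the
normalised symmetric co-occurrence probability over grey levels
``i, j = 1..Ng``; ``p_x`` is the row marginal (equal to the column marginal
by symmetry) with mean ``mu`` and standard deviation ``sigma``;
``p_{x+y}(k)`` and ``p_{x-y}(k)`` are the diagonal sum/difference
distributions; entropies use log base 2.  For the GLRLM block ``r(i, j)``
counts runs of grey level ``i`` and length ``j``, ``Ns`` is the total run
count and ``Nv`` the number of ROI voxels.

Naming follows the IBEX convention: ``Homogeneity`` is the inverse
difference (1/(1+|i-j|) weighting) and ``Homogeneity2`` the inverse
difference moment (1/(1+(i-j)^2) weighting).

On a zero-variance (single-grey-level) ROI, Correlation, the two information
measures of correlation and InverseVariance have no defined value and are
returned as NaN; downstream robustness statistics exclude such lesions with
a logged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .geometry import max_pairwise_distance
from .texture import (DiscretizationConfig, TextureMatrices, build_matrices,
                      discretize)
from .volume import IntensityVolume, RoiMask, voxel_centers_mm

GLRLM_FEATURES: tuple[str, ...] = (
    "GLNU", "HGLRE", "LRE", "LRHGLE", "LRLGLE", "LGLRE",
    "RLNU", "RunPercentage", "SRE", "SRHGLE", "SRLGLE",
)

GLCM_FEATURES: tuple[str, ...] = (
    "AutoCorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceEntropy", "Dissimilarity",
    "Energy", "Entropy", "Homogeneity", "Homogeneity2",
    "InformationMeasureCorrel1", "InformationMeasureCorrel2",
    "InverseDifferMomentNormal", "InverseDifferNormal", "InverseVariance",
    "MaxProbability", "SumAverage", "SumEntropy", "SumVariance",
)

TEXTURE_FEATURES: tuple[str, ...] = GLRLM_FEATURES + GLCM_FEATURES
MORPHOLOGY_FEATURES: tuple[str, ...] = ("Max3DDiameter", "NumberOfVoxels", "Volume")

#: GLCM features whose formulas raise grey-level deviations to powers 3-4;
#: contrasted with the inverse-difference ("homogeneity") family in
#: robustness analyses.
CLUSTER_FAMILY: tuple[str, ...] = ("ClusterProminence", "ClusterShade",
                                   "ClusterTendency")
HOMOGENEITY_FAMILY: tuple[str, ...] = ("Homogeneity", "Homogeneity2",
                                       "InverseDifferNormal",
                                       "InverseDifferMomentNormal")


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(m: TextureMatrices) -> dict[str, float]:
    """The 21 co-occurrence features from a normalised symmetric GLCM."""
    if m.glcm is None:
        raise DomainError("TextureMatrices has no GLCM")
    p = np.asarray(m.glcm, dtype=np.float64)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)                       # = py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal distributions
    ksum = (ii + jj).astype(int)             # 2..2Ng
    kdiff = np.abs(ii - jj).astype(int)      # 0..Ng-1
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)

    autocorr = float((ii * jj * p).sum())
    dev = ii + jj - 2.0 * mu
    contrast = float(((ii - jj) ** 2 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p * p).sum())
    entropy = float(-_xlog2(p).sum())
    sum_average = float((k_sum * p_sum).sum())

    hxy = entropy
    hx = float(-_xlog2(px).sum())
    pxpy = np.outer(px, px)
    valid = pxpy > 0
    hxy1 = float(-(p[valid] * np.log2(pxpy[valid])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())

    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
        imc1 = (hxy - hxy1) / hx if hx > 0 else np.nan
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        off = kdiff > 0
        inv_var = float((p[off] / (ii - jj)[off] ** 2).sum())
    else:
        correlation = imc1 = imc2 = inv_var = np.nan

    return {
        "AutoCorrelation": autocorr,
        "ClusterProminence": float((dev ** 4 * p).sum()),
        "ClusterShade": float((dev ** 3 * p).sum()),
        "ClusterTendency": float((dev ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "Dissimilarity": dissimilarity,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "InformationMeasureCorrel1": float(imc1),
        "InformationMeasureCorrel2": float(imc2),
        "InverseDifferMomentNormal": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "InverseDifferNormal": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float(inv_var),
        "MaxProbability": float(p.max()),
        "SumAverage": sum_average,
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumVariance": float(((k_sum - sum_average) ** 2 * p_sum).sum()),
    }


def glrlm_features(m: TextureMatrices, n_voxels: int | None = None) -> dict[str, float]:
    """The 11 run-length features from a direction-summed GLRLM.

    ``RunPercentage`` divides the total run count by
    ``n_voxels * n_directions``, consistent with the summed-matrix
    convention (each direction contributes up to one run per voxel).
    """
    if m.glrlm is None:
        raise DomainError("TextureMatrices has no GLRLM")
    if n_voxels is None:
        n_voxels = m.n_foreground
    r = np.asarray(m.glrlm, dtype=np.float64)
    ng, nr = r.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nr + 1, dtype=np.float64)[None, :]
    ns = r.sum()
    if ns == 0:
        raise DomainError("empty GLRLM")
    return {
        "GLNU": float((r.sum(axis=1) ** 2).sum() / ns),
        "HGLRE": float((r * i ** 2).sum() / ns),
        "LRE": float((r * j ** 2).sum() / ns),
        "LRHGLE": float((r * i ** 2 * j ** 2).sum() / ns),
        "LRLGLE": float((r * j ** 2 / i ** 2).sum() / ns),
        "LGLRE": float((r / i ** 2).sum() / ns),
        "RLNU": float((r.sum(axis=0) ** 2).sum() / ns),
        "RunPercentage": float(ns / (n_voxels * m.n_directions)),
        "SRE": float((r / j ** 2).sum() / ns),
        "SRHGLE": float((r * i ** 2 / j ** 2).sum() / ns),
        "SRLGLE": float((r / (i ** 2 * j ** 2)).sum() / ns),
    }


def morphology_features(mask: RoiMask, spacing=None) -> dict[str, float]:
    """Max 3D diameter (mm), voxel count and volume (cm^3) of a mask.

    The diameter is the maximum pairwise Euclidean distance between surface
    voxel centres (surface = foreground voxels with a face-adjacent
    background neighbour, grid borders counting as background).
    """
    if mask.is_empty():
        raise DomainError("empty mask has no morphology")
    spacing = tuple(mask.spacing if spacing is None else spacing)
    n = mask.n_voxels
    voxel_mm3 = float(np.prod(spacing))
    eroded = ndimage.binary_erosion(mask.values)     # 6-connected, border=0
    surface = mask.values & ~eroded
    pts = voxel_centers_mm(surface, spacing)
    return {
        "Max3DDiameter": max_pairwise_distance(pts),
        "NumberOfVoxels": float(n),
        "Volume": n * voxel_mm3 / 1000.0,
    }


@dataclass
class FeatureVector:
    """All 32 texture features plus morphology for one ROI, with provenance."""

    features: dict[str, float]
    lesion_id: str = ""
    reader_id: str = ""
    shape_tag: str = "manual"
    mode: str = "3D"

    def __post_init__(self) -> None:
        missing = [f for f in TEXTURE_FEATURES + MORPHOLOGY_FEATURES
                   if f not in self.features]
        if missing:
            raise DomainError(f"feature vector is missing {missing}")

    def __getitem__(self, name: str) -> float:
        return self.features[name]

    def texture(self) -> dict[str, float]:
        return {f: self.features[f] for f in TEXTURE_FEATURES}

    def to_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {
            "lesion_id": self.lesion_id, "reader_id": self.reader_id,
            "shape_tag": self.shape_tag, "mode": self.mode,
        }
        out.update({f: self.features[f] for f in TEXTURE_FEATURES + MORPHOLOGY_FEATURES})
        return out


def extract_features(
    volume: IntensityVolume,
    mask: RoiMask,
    config: DiscretizationConfig | None = None,
    mode: str = "3D",
    lesion_id: str = "",
) -> FeatureVector:
    """Full 32-feature + morphology vector for one ROI.

    Deterministic for fixed inputs; texture features depend only on the
    in-mask bin labels, so they are invariant to rigid whole-voxel
    translations of identical image content.
    """
    d = discretize(volume, mask, config)
    m = build_matrices(d, mode=mode)
    feats: dict[str, float] = {}
    feats.update(glrlm_features(m))
    feats.update(glcm_features(m))
    feats.update(morphology_features(mask))
    return FeatureVector(features=feats, lesion_id=lesion_id,
                         reader_id=mask.reader_id, shape_tag=mask.shape_tag,
                         mode=mode)
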