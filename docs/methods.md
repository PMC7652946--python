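# Methods

This note documents the models, conventions and numerical choices behind
`texrobust`, and what the synthetic cohort does and does not establish about
real CT data.

## Synthetic lesion phantoms

Clinical liver-metastasis CT with paired reader segmentations is not
redistributable, so the package ships a generator that emulates the relevant
structure of such a dataset.

**Image model.** A lesion phantom is a 3D HU grid on an anisotropic
CT-like lattice (default spacing 0.8 × 0.8 × 3.0 mm: near-isotropic
in-plane pixels, thick axial slices). The background is a portal-venous
liver level (default 110 HU, drawn per lesion from 100–120 HU) plus a
stationary correlated Gaussian texture: white noise smoothed with a Gaussian
kernel of physical width `texture_correlation_length` (1.5–3 mm) and
rescaled to marginal SD `noise_sd` (8–15 HU). The lesion is hypodense
(default 60 HU, drawn from 45–75 HU); its indicator is blended into the
background after Gaussian blurring of width `boundary_blur_sigma`
(0.5–1.5 mm), producing the blurred, low-contrast interface that makes these
lesions hard to contour. All HU are clamped to the physical CT range
[−1024, 3071]. The correlated Gaussian field is the simplest model that
yields non-degenerate GLCM/GLRLM statistics; it is a stand-in, not a claim
about tumour biology.

**Shape model.** The ground-truth mask is a smoothly deformed sphere:
radius `R(u) = R₀ · clip(1 + a·f(u), 0.3, 1.7)` where `f` is a smooth
random field on the sphere (a superposition of six long-wavelength cosine
waves, empirically centred and peak-normalised to max |f| = 1 on a fixed
512-point Fibonacci quadrature) and `a = shape_irregularity ∈ [0, 1)`
(default draw 0.05–0.20). Peak normalisation makes `a` a hard bound on the
relative radius perturbation, so the realised maximum 3D diameter stays
within ~`a` of the 2·R₀ target. Target diameters are drawn uniformly from
10–80 mm, the lesion-size range the cohort emulates.

**Reader model.** A simulated reader's mask is the truth with its boundary
displaced along the outward normal: a voxel belongs to the reader's mask iff
its signed Euclidean distance to the truth boundary (EDT in mm, negative
inside) is ≤ the local displacement

```
d(u) = radial_bias + radial_jitter_sd · w(u) · g(u),
w(u) = 1 + (z_partial_volume_weight − 1) · u_z²
```

with `g` an independent smooth unit-RMS zero-mean field on the sphere
(angular roughness set by `jitter_smoothness`, default 0.3). The polar
weighting `w` is the partial-volume mechanism: on thick axial slices the
boundary is hardest to place on the most peripheral (polar) slices of the
lesion, and without it an isotropic jitter produces the *wrong ordering*
of 2D vs 3D agreement (2D average Hausdorff worse than 3D). Two safeguards
keep the simulation well-posed: the random jitter is clipped at ±0.35 of
the lesion's equivalent radius (so small lesions cannot empty by chance),
and a realisation that still fragments the mask is redrawn with a
deterministically derived seed (at most 5 attempts), keeping cohorts
bit-reproducible. An extreme deliberate `radial_bias` can still empty the
mask, which raises a `PerturbationError` as it should.

**Default reader pair and calibration.** Reader 1 over-segments slightly
(bias +0.4 mm), reader 2 under-segments (−0.4 mm); both carry 0.9 mm
equatorial jitter with polar weight 8. These defaults were calibrated once,
on a pilot cohort, to land the median 3D inter-reader Dice in the
0.75–0.85 band with clearly better 2D agreement — the regime reported for
manual contouring of colorectal liver metastases — and were then frozen.
A 70-lesion cohort under these defaults gives median Dice ≈ 0.81 (3D) vs
≈ 0.96 (2D) and median average Hausdorff ≈ 2.7 mm (3D) vs ≈ 0.85 mm (2D).

**Seed discipline.** All randomness flows from one `master_seed` through
`numpy.random.SeedSequence` spawning (one child per lesion and per reader),
so cohorts are bit-identical across runs and the two readers' jitters are
independent.

**What passing tests do and do not show.** The generator reproduces the
*geometry* of the inter-reader problem (correlated contours, partial-volume
asymmetry between 2D and 3D, size-dependent grids) and gives textures rich
enough for all 32 features to be non-degenerate. It does not model CT
physics (reconstruction kernels, beam hardening), lesion rim enhancement,
confluent lesions or reader slice-selection idiosyncrasies; cohort-level
numbers (median Dice, per-feature MRC/ICC) are therefore qualitative
mirrors of clinical values, not reproductions.

## ROI derivation

* **Largest axial cross-section**: the single z-slice with maximal
  foreground area; ties broken by the lowest z index.
* **Circles** are computed in physical mm from in-plane voxel centres.
  Enclosing: exact minimum bounding circle of the foreground centres
  (shapely). Inscribed: the foreground voxel centre maximising the exact
  Euclidean distance to the background *region* (union of background pixel
  rectangles, grid exterior included), computed by brute force over
  boundary-adjacent background pixels; ties broken lexicographically.
  Rasterisation rule, both directions: a voxel belongs to a circle iff its
  centre lies within the radius (+1e−9 mm guard), which guarantees
  `inscribed ⊆ manual ⊆ enclosing` voxelwise.
* Exclusion rule: lesions whose largest within-slice diameter is < 10 mm
  are dropped (exactly 10 mm is retained). This calliper-style diameter is
  the max in-plane centre-to-centre distance **plus one pixel width**, so a
  single voxel measures one pixel across; the `Max3DDiameter` *feature*
  stays centre-to-centre (a single voxel has diameter 0).

## Texture extraction

* Discretization: fixed window −200..279 HU = 480 grey levels in 32
  uniform 15-HU bins; `label = floor((clamp(HU) − hu_min)/15) + 1`, bins
  left-closed/right-open with the last bin closed. Out-of-window HU are
  clamped inward and counted. Custom windows must divide evenly into the
  requested bins.
* Directions: offset-1 unique directions up to sign — 13 in 3D, 4 in-plane
  in 2D — in voxel steps (no resampling; anisotropy is deliberate).
  Per-direction matrices are **summed** into one matrix before
  normalisation and feature computation; per-direction averaging of a
  normalised GLCM would give identical features, so the summed convention
  is also the numerically simplest.
* GLCM: symmetric (both orderings counted), normalised to probabilities.
  GLRLM: maximal runs of equal bin per direction, truncated at the mask
  boundary; the direction-summed matrix conserves
  `Σ j·r(i,j) = n_directions × n_voxels`.
* `RunPercentage = total runs / (n_voxels × n_directions)` — under the
  summed-matrix convention each direction can contribute at most one run
  per voxel, so the ratio stays in (0, 1].
* Naming: `Homogeneity` is the inverse difference, `Homogeneity2` the
  inverse difference moment; entropies use log₂.
* Degenerate ROIs: a single-grey-level ROI leaves Correlation, both
  information measures of correlation, and InverseVariance undefined; they
  return NaN and downstream MRC/ICC exclude those lesions with a reported
  `n_valid`. A single-voxel ROI has no co-occurring pairs and raises.

## Agreement and robustness statistics

* Boundaries for the average Hausdorff distance are voxel centres with a
  face-adjacent background neighbour (6-connectivity in 3D, 4-connectivity
  in-plane for 2D masks; the grid border counts as background). The
  *symmetric* average `[Σ min-dist(∂A→∂B) + Σ min-dist(∂B→∂A)] /
  (|∂A|+|∂B|)` is used so the metric is argument-symmetric.
* 2D similarity compares the two readers' largest cross-sections in-plane;
  if the readers chose different slices the masks are overlaid at a common
  z first (slice choice is part of reader variability, but the metric is
  in-plane mm).
* MRC averages |(RF_R1 − RF_R2)/RF_R1| — individual changes are signed
  (and the signed denominator is kept for negative-valued features such as
  ClusterShade), the absolute value enters only at aggregation. Lesions
  with RF_R1 = 0 or non-finite values are excluded per feature, with the
  exclusion count reported; no outlier truncation is applied.
* ICC(2,1) is computed from the explicit two-way ANOVA mean squares; the
  consistency form (rater-variance term dropped) is available behind
  `form="consistency"` but absolute agreement is the default and the one
  reported. Zero between-lesion variance or fewer than 3 complete pairs
  yields NaN.
* Companion tests use scipy: Wilcoxon signed-rank (zeros dropped, exact
  null for ≤ 25 untied differences, normal approximation with continuity
  correction otherwise), Spearman rank correlation (average ranks,
  t-approximation p), and OLS slope/intercept for the size-vs-agreement
  regression with Evans strength labels (|rho| < 0.20 very weak, < 0.40
  weak, < 0.60 moderate, < 0.80 strong, else very strong). No multiple-
  testing correction is applied; p-values are reported raw at α = 0.05.
* Circular-ROI comparison: per patient the *main lesion* is the one with
  the largest 3D reader-1 volume. All three MRCs (R1 vs R2, R1 vs
  enclosing, R1 vs inscribed) use R1 manual values as the denominator;
  `inter_reader_preponderant` flags features whose inter-reader MRC is ≥
  both circle MRCs.

## Pipeline

`run_pipeline` composes the stages from one config (synthetic or
NIfTI-labelmap input), writes CSV/JSON reports plus an exclusion log and a
run manifest (config, seeds, version, per-stage counts), and is
bit-deterministic in synthetic mode. In labelmap mode there is no ground
truth, so exclusion diameters are measured on the reader-1 mask; unreadable
lesions are logged and skipped, and the run aborts only if none survives.
Synthetic lesions are assigned round-robin to `n_patients` (default 17) so
the main-lesion selection of the circular arm has patient structure.

## Problem sizes and limitations

The default study conditions — 70 lesions, 10–80 mm, two readers — run end
to end in about a minute; the test suite's cohort-level checks reuse one
session-scoped 70-lesion cohort, and statistical-recovery checks use n = 500
simulated feature pairs (ICC) and n = 70 (MRC). Known limitations: no CT
acquisition-parameter axis, no confluent or rim-enhancing lesions, no mesh
contours (the pipeline operates on voxel labelmaps), and the classical/95%
Hausdorff variants are intentionally not implemented (the average form is
the global-discrepancy measure of interest).
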