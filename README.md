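# texrobust

Inter-reader robustness analysis of second-order radiomic texture features
from CT liver-lesion contours.

## The problem

Radiomic texture features are candidate imaging biomarkers for metastatic
colorectal cancer, but they are computed from *manually contoured* regions of
interest — and two readers never draw exactly the same contour, especially on
hypodense liver lesions with blurred boundaries. Before a feature can enter a
predictive model, one must know how much of its variance is just contouring
noise. `texrobust` is a library (plus a thin CLI) for medical-physics and
radiomics researchers that quantifies this:

* **contour agreement** between two readers, per lesion, with the Dice
  coefficient `DC = 2|A∩B| / (|A|+|B|)` and the symmetric **average Hausdorff
  distance** (mean nearest-boundary distance in mm) — for whole-lesion 3D
  ROIs and for single-slice 2D ROIs;
* **feature robustness**, per feature, with the **mean relative change**
  `MRC = meanₗ |(RF_R1 − RF_R2)/RF_R1|` (percent) and the intraclass
  correlation coefficient **ICC(2,1)** (two-way random effects, absolute
  agreement, single rater):

  `ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))`

  banded as poor (≤ 0.50), moderate (≤ 0.75), good (≤ 0.90) or excellent
  (> 0.90); a feature counts as *robust* when ICC > 0.90 **and** MRC < 10%;
* the **32 texture features** themselves — 21 grey-level co-occurrence
  (GLCM) and 11 grey-level run-length (GLRLM) features in their IBSI
  formulations, plus morphology (max 3D diameter, voxel count, volume) —
  extracted under a fixed discretization of 480 grey levels (−200..279 HU)
  in 32 bins, offset 1, symmetric counting, all 13 (3D) or 4 (in-plane 2D)
  directions summed into one matrix, no resampling;
* a **simplified-protocol comparison**: minimum enclosing and maximum
  inscribed circles derived from the manual 2D ROI, with the R1-referenced
  MRC of circles-vs-manual compared against the inter-reader MRC;
* a **synthetic cohort generator**: textured lesion phantoms (correlated
  Gaussian texture, smoothly deformed ellipsoids, blurred boundaries,
  10–80 mm diameters on anisotropic CT-like grids) with two simulated
  readers whose contours are correlated but not identical — so the whole
  pipeline is testable and reproducible without clinical data.

## Worked example

```bash
python examples/04_robustness_cohort.py
```

prints, for a 12-lesion synthetic cohort with the default reader model:

```
3D ROIs: median Dice 0.81 (IQR 0.78-0.85), median avg HD 2.79 mm
2D ROIs: median Dice 0.97 (IQR 0.95-0.97), median avg HD 0.74 mm

robust features 2D (13/32): GLNU, HGLRE, LGLRE, RunPercentage, ...
robust features 3D (8/32): GLNU, LRE, LRHGLE, LRLGLE, RunPercentage, ...

least stable features by 3D MRC:
ClusterProminence    30.4
SumVariance          27.0
ClusterTendency      27.0
ClusterShade         26.6
```

Read this as: the two simulated readers overlap ~81% voxelwise on whole
lesions but ~97% on the single largest slice (thick axial slices make the
peripheral-slice boundary genuinely ambiguous, so a 2D protocol suffers less
inter-reader variability); run-length emphasis features are stable between
readers, whereas the "cluster" features — whose formulas raise grey-level
deviations to the 3rd/4th power — amplify contouring noise the most.

The other examples each exercise one capability: `01_simulate_lesion.py`
(phantom + reader simulation + agreement metrics), `02_extract_features.py`
(3D vs 2D feature extraction), `03_circular_rois.py` (enclosing/inscribed
circles and their divergent feature shifts).

The same analysis runs from the shell on NIfTI labelmaps or synthetic
cohorts:

```bash
texrobust simulate --n-lesions 10 --seed 1 --out cohort/
texrobust run-all --config config.yaml
```

producing per-lesion feature CSVs, similarity CSV/JSON, the robustness table
(feature × {MRC, ICC, band, robust} for 2D and 3D), the circular-ROI
comparison, an exclusion log (lesions with axial diameter < 10 mm are
dropped) and a run manifest with all seeds.

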