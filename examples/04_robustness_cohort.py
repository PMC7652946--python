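"""Run the full inter-reader robustness analysis on a small synthetic cohort.

Generates 12 lesions with two simulated readers, extracts features from 3D
and 2D ROIs, and prints the contour-agreement summaries plus the per-feature
robustness table (MRC = mean relative change between readers, in percent;
ICC = intraclass correlation, absolute agreement).  A feature is "robust"
when ICC > 0.90 and MRC < 10%.
"""

import texrobust as tx

config = tx.PipelineConfig(input_mode="synthetic", n_lesions=12,
                           master_seed=1, n_patients=4,
                           output_dir="scratch/example_cohort")
results = tx.run_pipeline(config)

for mode, summary in results["stats_summary"]["similarity"].items():
    print(f"{mode} ROIs: median Dice {summary['dice_median']:.2f} "
          f"(IQR {summary['dice_iqr'][0]:.2f}-{summary['dice_iqr'][1]:.2f}), "
          f"median avg HD {summary['hausdorff_median_mm']:.2f} mm")

rob = results["robustness"]
robust_2d = rob.index[rob["robust_2d"]].tolist()
robust_3d = rob.index[rob["robust_3d"]].tolist()
print(f"\nrobust features 2D ({len(robust_2d)}/32): {', '.join(robust_2d)}")
print(f"robust features 3D ({len(robust_3d)}/32): {', '.join(robust_3d)}")
print("\nleast stable features by 3D MRC:")
print(rob["mrc_pct_3d"].sort_values(ascending=False).head(4).round(1).to_string())
print("\nHigher Dice / lower HD for 2D ROIs means a single-slice protocol "
      "suffers less inter-reader variability; the cluster-family features "
      "top the MRC ranking because their formulas amplify grey-level "
      "deviations to the 3rd/4th power.")
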