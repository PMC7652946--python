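"""Extract the 32 GLCM/GLRLM texture features from a 3D ROI and its largest
axial cross-section.

Intensities are discretized over the fixed window -200..279 HU (480 grey
levels in 32 bins of 15 HU); matrices are accumulated over 13 directions in
3D mode and the 4 in-plane directions in 2D mode.  The printed values show
how the same lesion yields different (but related) texture summaries in the
two modes.
"""

import texrobust as tx

spec = tx.LesionSpec(center=(35, 35, 14), target_diameter=30.0)
volume, truth = tx.generate_lesion_volume(spec, (71, 71, 29),
                                          tx.DEFAULT_SPACING, seed=11)

fv3 = tx.extract_features(volume, truth, mode="3D")
cross_section = tx.largest_axial_cross_section(truth)
fv2 = tx.extract_features(volume, cross_section, mode="2D")

print(f"{'feature':<28}{'3D ROI':>12}{'2D ROI':>12}")
for name in ("Contrast", "Correlation", "Entropy", "Energy", "Homogeneity",
             "ClusterProminence", "SRE", "LRE", "RunPercentage", "GLNU"):
    print(f"{name:<28}{fv3[name]:>12.4f}{fv2[name]:>12.4f}")
print(f"{'Max3DDiameter (mm)':<28}{fv3['Max3DDiameter']:>12.1f}")
print(f"{'Volume (cm^3)':<28}{fv3['Volume']:>12.2f}")
print(f"\n{len(fv3.texture())} texture features extracted per ROI; "
      "higher Contrast/Entropy = rougher texture, Homogeneity near 1 = "
      "smooth, RunPercentage near 1 = short runs (noisy texture).")
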