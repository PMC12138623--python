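"""Blank filtering, crude-vs-inoculated fold changes, and metabolite PCA.

The planted parent compound drops on inoculation while its microbial
transformation product rises; the paired Wilcoxon signed-rank test flags
both at the smallest p attainable with five replicate pairs per condition.
"""

from gutmetab.features import blank_filter, fold_change, pca_scores
from gutmetab.simulate import PARENT_ID, PRODUCT_ID, SimulationDesign, simulate_study

study = simulate_study(SimulationDesign(seed=1))
table = blank_filter(study.feature_table, min_ratio=3.0)
print(f"blank filter kept {table.features.shape[0]} of "
      f"{study.feature_table.features.shape[0]} features")

fc = fold_change(table)
for fid, label in ((PARENT_ID, "parent"), (PRODUCT_ID, "product")):
    row = fc.table.loc[fid]
    print(f"{label} ({fid}): log2FC = {row.log2fc:+.2f}, "
          f"signed-rank p = {row.p_value:.3g}")

scores, evr = pca_scores(table, n_components=2)
print(f"\nPCA on log10 peak areas: PC1 {100 * evr[0]:.1f}%, PC2 {100 * evr[1]:.1f}%")
crude = scores.loc[[s for s in scores.index if s.endswith("crude")], "PC1"].mean()
inoc = scores.loc[[s for s in scores.index if s.endswith("inoc")], "PC1"].mean()
print(f"PC1 centroid, crude extracts: {crude:+.2f}; inoculated: {inoc:+.2f}")
# Negative parent and positive product log2FC together are the abundance
# signature of a microbial biotransformation; the PC1 split shows inoculation
# reshapes the global metabolic profile.
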