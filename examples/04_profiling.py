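"""Non-targeted cultivar profiling: filter, normalize, correct, average,
log2, PCA, per-feature ANOVA and hierarchical clustering.

One cultivar is given a distinct metabolite family (15 features with a
+2 log2 effect); the analysis should isolate that cultivar on PC1 and call
the family's features significant after FDR adjustment.
"""
import numpy as np

import lcmsqc as L
from lcmsqc.synthdata import SyntheticConfig

design = L.cultivar_design(seed=8)  # 8 cultivars x 4 agronomic x 2 technical
family = {f"F{i + 1:04d}": {"class01": 2.0} for i in range(15)}
config = SyntheticConfig(
    n_features=150, n_batches=0, drift_amplitude=0.15,
    cv_injection=0.086, cv_extraction=0.006, cv_batch=0.0,
    class_effects=family, seed=21,
)
table, truth = L.simulate_feature_table(config, design)

kept, removal_log = L.filter_features(table, cv_max=0.30)
corrected, _ = L.apply_correction(L.normalize_by_weight(kept))
averaged = L.average_replicates(corrected, "technical", keep_qc=False)
logged = L.log2_transform(averaged)

X = logged.intensities.T  # samples x features
res = L.pca(X)
labels = logged.injections.loc[X.index, "class_label"]
anova = L.per_feature_anova(X, labels)

print(f"features retained by QC filter : {kept.intensities.shape[0]} "
      f"(removed {len(removal_log)})")
print(f"PC1/PC2 variance explained     : "
      f"{res.variance_explained[0]:.1%} / {res.variance_explained[1]:.1%}")
hits = anova.index[anova["q"] <= 0.01]
print(f"features with q <= 0.01        : {len(hits)}")
print(f"  of which in the spiked family: "
      f"{len(set(hits) & set(family))} / {len(family)}")

top_loadings = res.loadings["PC1"].abs().sort_values(ascending=False)
in_family = [f for f in top_loadings.index[:15] if f in family]
print(f"family features among top-15 |PC1 loadings|: {len(in_family)}")

by_cultivar = L.log2_transform(
    L.average_replicates(corrected, "technical+agronomic", keep_qc=False)
)
clu = L.cluster_heatmap(by_cultivar.intensities, png_path="heatmap.png")
print("cultivar dendrogram (Newick):", L.dendrogram_newick(clu, "columns"))
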