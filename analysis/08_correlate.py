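"""Cross-block correlation of group-level endpoints and DAM clustering.

Correlates group-mean abundances of top DAM features with per-group ROAV
scores and per-group antioxidant summaries (n = 4 group means — exact
r = 1 is attainable and p-values carry little evidence at this n), and
emits clustering orders for the DAM heatmap.
"""

import itertools
import json

import numpy as np
import pandas as pd

from common import CONFIG, SEED, outdir, preprocessed_study
from harvestomics import dam, flavor, integrate, preprocess, synthetic

out = outdir("correlate")

table, truth, _ = preprocessed_study()
groups = table.groups()
comparisons = {
    f"{ga} vs {gb}": dam.pairwise_dam(table, ga, gb)
    for ga, gb in itertools.combinations(groups, 2)
}
_, union = dam.integrate_comparisons(comparisons)
top_dams = union["feature_id"].head(8).tolist()

group_means = table.values.groupby(table.samples["group"]).mean().loc[groups]

odor, _ = synthetic.generate_odor_table(n_compounds=CONFIG["odor"]["n_compounds"],
                                        n_groups=4, seed=SEED)
odor["group"] = odor["group"].map(dict(zip(sorted(odor["group"].unique()), groups)))
roav = flavor.roav_frame(flavor.compute_roav(odor))
roav_block = roav.pivot_table(index="group", columns="compound_id", values="roav").loc[groups]
top_volatiles = roav_block.mean().sort_values(ascending=False).head(5).index

# one antioxidant-like summary per group: total abundance of spiked features
antioxidant_block = pd.DataFrame({
    "spiked_total": np.log2(group_means[[f for f in truth.dam_features
                                         if f in group_means.columns]]).sum(axis=1)
})

blocks = {
    "metabolite": group_means[top_dams],
    "flavor": roav_block[top_volatiles],
    "antioxidant": antioxidant_block,
}
pearson = integrate.correlation_matrix(blocks, method="pearson")
spearman = integrate.correlation_matrix(blocks, method="spearman")
pearson.to_csv(out / "correlations_pearson.csv", index=False)
spearman.to_csv(out / "correlations_spearman.csv", index=False)
strong = pearson[pearson["r"].abs() > 0.9]
print(f"{len(pearson)} between-block pairs (n = {pearson['n'].iloc[0]} group means); "
      f"{len(strong)} with |r| > 0.9")

model_ready = preprocess.autoscale(preprocess.impute_and_log2(table))
dam_cols = [f for f in union["feature_id"] if f in model_ready.values.columns]
heat = integrate.cluster_heatmap(model_ready.values[dam_cols])
with open(out / "heatmap_orders.json", "w") as fh:
    json.dump({"row_order": heat["row_order"], "col_order": heat["col_order"]}, fh, indent=2)
print("sample dendrogram order:", heat["row_order"])
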