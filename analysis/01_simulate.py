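"""Generate the synthetic study: intensity table, odor table, assay curves.

Emulates a 4-harvest-group x 3-replicate design with 4 pooled-QC
injections, 200 features of which 60 carry a +/-2 log2-unit shift in the
last group, multiplicative injection-order drift, an odor table with known
OAV ranking, and two scavenging assays with known IC50.
"""

import json

import pandas as pd

from common import CONFIG, SEED, outdir, simulate_study
from harvestomics import synthetic

out = outdir("data")

table, truth = simulate_study()
table.to_csv(out / "feature_table.csv")
truth.to_json(out / "truth.json")
print(f"feature table: {table.values.shape[0]} injections x {table.n_features} features "
      f"({table.n_qc} QC rows, {len(truth.dam_features)} spiked features)")

odor, odor_truth = synthetic.generate_odor_table(
    n_compounds=CONFIG["odor"]["n_compounds"], n_groups=4, seed=SEED)
odor.to_csv(out / "odor_table.csv", index=False)
odor_truth.to_json(out / "odor_truth.json")
print(f"odor table: {odor['compound_id'].nunique()} compounds x "
      f"{odor['group'].nunique()} groups")

curves = {}
for i, (assay, ic50) in enumerate(CONFIG["assays"]["true_ic50"].items()):
    curve = synthetic.generate_assay_curves(
        assay, true_ic50=ic50, hill_slope=CONFIG["assays"]["hill_slope"],
        noise_sd=CONFIG["assays"]["noise_sd"], seed=SEED + i + 1)
    pd.DataFrame({
        "assay": assay, "concentration": curve.concentrations,
        "a_sample": curve.a_sample, "a_0": curve.a_0,
    }).to_csv(out / f"assay_{assay}.csv", index=False)
    curves[assay] = ic50
print(f"assay curves written with true IC50 {curves} mg/mL")

with open(out / "config.json", "w") as fh:
    json.dump(CONFIG, fh, indent=2)
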