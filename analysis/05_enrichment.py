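"""Superclass composition and pathway over-representation of the DAM union.

Annotates the detected features with a toy superclass/pathway map and runs
the hypergeometric enrichment test with BH correction.
"""

import itertools

from common import CONFIG, SEED, outdir, preprocessed_study
from harvestomics import dam, enrichment, synthetic

out = outdir("enrichment")

table, truth, _ = preprocessed_study()
groups = table.groups()
comparisons = {
    f"{ga} vs {gb}": dam.pairwise_dam(table, ga, gb)
    for ga, gb in itertools.combinations(groups, 2)
}
_, union = dam.integrate_comparisons(comparisons)
dam_ids = union["feature_id"].tolist()

annotation = synthetic.generate_annotation(table.feature_ids, seed=SEED,
                                           **CONFIG["annotation"])
annotation.to_tsv(out / "pathway_map.tsv")

composition = dam.superclass_composition(dam_ids, annotation)
composition.to_csv(out / "superclass_composition.csv", index=False)
top = composition.iloc[0]
print(f"superclass composition of {len(dam_ids)} DAMs: top class "
      f"\"{top['superclass']}\" at {top['percent']:.2f}%")

records = enrichment.enrich_pathways(dam_ids, table.feature_ids, annotation.pathways)
frame = enrichment.enrichment_frame(records)
frame.to_csv(out / "enrichment.csv", index=False)
n_sig = int(frame["significant"].sum())
print(f"enrichment: {len(frame)} pathways tested, {n_sig} significant at q <= 0.05")
print(frame.head(3).to_string(index=False))
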