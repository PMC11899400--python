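"""Unsupervised and supervised multivariate views of the corrected table.

PCA for overview, PLS-DA across all four harvest groups with sevenfold
cross-validated Q2 and a 200-iteration label-permutation test of R2Y/Q2.
"""

import json

import pandas as pd

from common import CONFIG, SEED, outdir, preprocessed_study
from harvestomics import chemometrics, preprocess

out = outdir("multivariate")

table, truth, _ = preprocessed_study()
model_ready = preprocess.autoscale(preprocess.impute_and_log2(table))
X = model_ready.values.to_numpy()
labels = model_ready.samples["group"].tolist()

pca = chemometrics.fit_pca(X, n_components=2)
print("PCA: PC1 explains {:.1f}%, PC2 {:.1f}% of the variance".format(
    *(100 * pca.explained_variance)))

spec = {"method": "plsda", "n_components": CONFIG["model"]["n_components"]}
plsda = chemometrics.fit_plsda(X, labels, CONFIG["model"]["n_components"])
q2 = chemometrics.cross_validate_q2(X, labels, spec, k=CONFIG["model"]["cv_folds"], seed=SEED)
perm = chemometrics.permutation_test(X, labels, spec, n_perm=CONFIG["model"]["n_perm"],
                                     seed=SEED, k=CONFIG["model"]["cv_folds"])
print(f"PLS-DA: R2Y = {plsda.r2y:.3f}, Q2 = {q2:.3f}")
print(f"permutation test ({perm.n_perm} iterations): p(R2Y) = {perm.p_r2y:.4f}, "
      f"p(Q2) = {perm.p_q2:.4f}")

scores = pd.DataFrame(plsda.scores, index=model_ready.values.index,
                      columns=[f"t{a + 1}" for a in range(plsda.n_components)])
scores["group"] = labels
scores.to_csv(out / "plsda_scores.csv")
pd.DataFrame(pca.scores, index=model_ready.values.index,
             columns=["PC1", "PC2"]).to_csv(out / "pca_scores.csv")
with open(out / "diagnostics.json", "w") as fh:
    json.dump({
        "pca_explained_variance": pca.explained_variance.tolist(),
        "r2x": plsda.r2x, "r2y": plsda.r2y, "q2": q2,
        "permutation": {"n_perm": perm.n_perm, "p_r2y": perm.p_r2y, "p_q2": perm.p_q2},
    }, fh, indent=2)
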