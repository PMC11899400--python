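# harvestomics

Analysis pipeline for harvest-time studies of aromatic herb teas that
combine untargeted metabolomics, volatile/flavor profiling and antioxidant
assays. It is written for the analyst who has a sample × feature intensity
table with pooled-QC injections, a volatile compound table with odor
thresholds, and dose–response absorbance series — and who wants the
standard chemometric workflow on top of them, fully tested:

- **Preprocessing** — pooled-QC LOESS (QC-RLSC) injection-order drift
  correction, QC RSD > 30% stability filtering, internal-standard
  normalisation, half-minimum imputation + log2, autoscaling.
- **Chemometrics** — PCA, PLS-DA and two-class OPLS-DA implemented from
  first principles (NIPALS / orthogonal filtering), VIP scores, stratified
  sevenfold cross-validated Q² and label-permutation validation.
- **Differential screening** — per-pair calls at VIP > 1 and t-test
  p < 0.05 on log2 intensities, volcano tables, upset-style integration
  across comparisons, superclass composition.
- **Enrichment** — hypergeometric pathway over-representation with BH
  correction.
- **Flavor** — relative odor activity values (ROAV; the most odor-active
  compound per group scores 100, ROAV > 1 marks a key odorant), Kovats
  retention-index interpolation, descriptor radar grading, bipartite
  compound–descriptor networks.
- **Antioxidant endpoints** — scavenging % = 100·(1 − A_sample/A₀), IC50
  by bracketing interpolation or 4PL fit, FRAP conversion through a linear
  Fe²⁺ calibration.
- **Integration** — cross-block correlations on group-level endpoints and
  deterministic cluster-heatmap orderings.

A first-class synthetic-data module generates every input with recorded
ground truth (spiked log2 effects, drift coefficients, true IC50, true OAV
ranking), so the whole chain is testable by parameter recovery without any
external data. See `docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tables under `results/`. From the repository root:

```sh
cd analysis
python 01_simulate.py
python 02_preprocess.py
python 03_multivariate.py
python 04_dam_screen.py
```

which prints, among other lines:

```
feature table: 16 injections x 200 features (4 QC rows, 60 spiked features)
QC RSD median before 16.8% -> after 0.0%
correction reduced QC RSD for 100.0% of features
PCA: PC1 explains 36.7%, PC2 13.5% of the variance
PLS-DA: R2Y = 0.594, Q2 = 0.292
permutation test (200 iterations): p(R2Y) = 0.0149, p(Q2) = 0.0149
G1 vs G4: 32 up / 31 down (63 DAMs)
union: 102 DAMs, 77 consistent across >= 2 comparisons
recovery (G1 vs G4): sensitivity 1.00 on 60 spiked features
```

Reading this: the pooled-QC LOESS correction removed the simulated
injection-order drift (QC RSD collapses; with only 4 QC injections the
smoother nearly interpolates them, hence ~0%); the four harvest groups are
separable but, at n = 3 per group, with modest cross-validated Q²; the
label-permutation test still rejects the no-structure null (p ≈ 0.015);
and the VIP > 1 & p < 0.05 screen recovers every spiked feature in the
comparison that contrasts the affected group. Scripts 05–08 continue with
enrichment, ROAV/flavor networks, IC50/FRAP endpoints and cross-block
correlations, e.g.:

```
DPPH: true IC50 1.20 mg/mL, interpolation 1.267, 4PL 1.217 (1.4% off truth)
key compounds (ROAV > 1) per group: {'G1': 16, 'G2': 15, 'G3': 13, 'G4': 22}
```

The same chain is available as one call:

```python
from harvestomics import run_pipeline
results = run_pipeline({"seed": 7}, outdir="results/run")
print(results["plsda"].r2y, results["ic50"]["DPPH"].ic50)
```

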