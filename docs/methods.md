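# Methods

This note documents the models, defaults and numerical choices behind
`harvestomics`, and what the synthetic study the package ships can and
cannot demonstrate.

## Study design being emulated

The pipeline targets a harvest-time comparison of an aromatic herb tea:
four harvest groups with three biological replicates each, profiled by
untargeted LC–MS (intensity table), headspace GC (volatile/odor table) and
spectrophotometric antioxidant assays (DPPH, ABTS, FRAP). Pooled-QC
injections — an equal-volume mixture of all study samples injected at the
start, the end and evenly through the batch — anchor drift correction and
feature-stability filtering.

Because no raw feature tables are publicly deposited for such studies, the
`synthetic` module generates every input with recorded ground truth, and
all downstream claims in the test suite are parameter-recovery claims
against that truth.

## Synthetic data model

Intensities are log-normal: each feature draws a baseline log2 abundance
uniformly in [10, 20]; replicate noise is multiplicative log-normal with
unit mean and coefficient of variation `noise_cv` (default 0.1, a typical
QC-grade measurement CV). Differential features receive an additive shift
of `effect_log2` (default 2, alternating sign) in the last group.
Instrument drift multiplies every intensity by a smooth, strictly positive
per-feature factor over injection order: 1 + a·(x − ½) + b·sin(2πx + φ)
with |a|, |b| ≤ `drift_amplitude` (default 0.3), the structure that
QC-based LOESS correction is designed to remove. QC rows carry the pooled
mean profile of all groups, times drift, times noise.

Defaults follow the emulated study: 4 groups × 3 replicates + 4 QC
injections and 200 features, of which 60 (30%) are differential — matching
the per-pair differential fractions such studies report (roughly 30–40% of
identified metabolites). The differential fraction matters: it sets how
much weight mass the discriminant model concentrates on true effects and
therefore whether the VIP > 1 gate adds specificity beyond the t-test.

The odor-table generator draws per-group peak areas (10³–10⁷) and odor
thresholds (10⁻²–10¹) on log-uniform scales and records the true
peak-area/threshold ranking. Assay curves follow a four-parameter logistic
from 0 to 100% scavenging centred on a known IC50 with Gaussian noise in
percentage points, clipped to [0, 100]; absorbances are back-computed with
a unit control so the assay module recomputes scavenging from raw
readings.

What the generator does *not* emulate: peak picking and alignment
artefacts, missingness mechanisms other than zeros, correlated feature
blocks (features are independent given group), retention-time drift, or
matrix effects. Passing recovery tests therefore show the estimators are
correct under the stated noise model, not that they are robust to every
real-data pathology.

## Preprocessing

Default chain: QC-LOESS drift correction → QC-RSD filter →
(optional internal-standard normalisation) → half-minimum imputation +
log2 → autoscaling. Each stage takes and returns the same table type, so
the order is configurable.

Drift correction follows the QC-RLSC convention: per feature, a locally
weighted degree-1 regression with tricube weights (span 0.75, three
robustifying iterations) of QC intensity on injection order; every
injection is rescaled by (median fitted QC level / drift at its own
order), which preserves the feature's median QC level. Beyond the
outermost QC injections the drift curve is clamped to the nearest fitted
value rather than extrapolated. At least 4 QC injections are required;
with exactly 4 the smoother nearly interpolates the QC points, so post-
correction QC RSD is close to zero — more QC injections make the QC RSD
statistic more informative. If the fitted drift is non-positive anywhere
(pathological fits on near-zero features), the feature falls back to a
constant global-median scaling and the event is logged.

The stability filter removes features whose QC RSD (sample sd / mean ×
100) exceeds 30%, the conventional untargeted-QC threshold. Imputation
replaces zeros/missing with half the feature's smallest positive value
(common metabolomics default; features with no positive values are
dropped). Autoscaling centres and scales to unit sample variance;
zero-variance features are dropped with a warning.

## Discriminant models

PCA is the SVD of the column-centred matrix; explained variance is the
squared-singular-value fraction.

PLS-DA is NIPALS PLS2 on one-hot class labels with classic deflation of
both blocks (tolerance 1e-10 on the relative score change, 500 iterations,
non-convergence logged). OPLS-DA is restricted to two groups, as used for
pairwise screening: orthogonal components are extracted by the
filter-then-project construction (weight from the label covariance,
orthogonal weight as the label-orthogonal part of the loading), the matrix
is deflated, and a single predictive component is fit on the filtered
matrix. For a single response, predictions of a 1+k OPLS model equal a
(1+k)-component PLS model — an identity the test suite asserts at 1e-6 and
the reason `n_orthogonal=0` reduces exactly to one-component PLS-DA.
Component signs follow the largest-|weight|-positive convention so fits
are reproducible across runs and libraries.

VIP uses the standard projection-weighted formula over predictive
components only (VIP_pred for OPLS, common chemometrics practice), so the
mean squared VIP is 1 by construction.

Q2 is 1 − PRESS/TSS over held-out one-hot responses under stratified
k-fold cross-validation, k = 7 by default (the convention in SIMCA-style
workflows); folds are dealt round-robin within each group from a seeded
shuffle because group sizes of 3 make unstratified folds degenerate.
Permutation validation refits R2Y and the cross-validated Q2 under
`n_perm` label permutations (default 200) and reports add-one empirical
p-values, p = (1 + #{permuted ≥ observed})/(n_perm + 1), so the smallest
attainable p is 1/(n_perm + 1). The orthogonal-component count "auto" rule
adds components while CV Q2 improves by more than 0.01, capped at 5.

## Differential screening

Per pair: a feature is differential when its OPLS-DA VIP exceeds 1 *and* a
two-sided equal-variance t-test on the log2 intensities gives p < 0.05
(Welch optional). Fold change is reported as log2 of the raw group-mean
ratio (second group over first) — the common reporting convention, while
tests run on log2 values. Benjamini–Hochberg q-values are reported
alongside but do not enter the default call, mirroring the raw-p screening
criterion. Features with zero variance in both groups and equal means get
p = 1 by convention. Upset integration counts disjoint membership classes
over the pairwise DAM sets; features flagged in ≥ 2 comparisons (a
configurable floor) are marked consistent candidates.

## Enrichment

One-sided hypergeometric upper-tail test per pathway (P[X ≥ k]) against
the background of all annotated features surviving preprocessing, BH
correction across tested pathways. The hypergeometric choice is an
assumption: bubble-chart enrichment workflows rarely name their statistic,
and over-representation by hypergeometric test is the field standard. The
bundled annotation is a deterministic toy map; its pathways are random
subsets, so enrichment on the synthetic study is expected to be null — the
tests validate the statistic against exact enumeration, not a biological
signal.

## ROAV

The default ROAV is the OAV-ratio form: ROAV_B = 100·(Peak_B/T_B)/
(Peak_A/T_A) with reference A the compound maximising Peak/T in scope
(per group by default; global optional). This guarantees the reference
scores exactly 100 and every score lies in (0, 100], and ranking by ROAV
equals ranking by OAV. The literature sometimes prints the formula as a
product, Peak_B·T_B/(Peak_A·T_A), with the smallest-threshold compound as
reference; that form breaks the ≤ 100 bound whenever the smallest-
threshold compound is not the most odor-active, so it is kept only as
`literal_eq3` mode for comparison. Compounds with ROAV strictly above 1
are key flavor compounds (a score of exactly 1 is not key).

Retention indices interpolate linearly between bracketing n-alkanes,
RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n)), with no extrapolation.
Descriptor radar grades map per-group descriptor counts to 1–5 by
equal-width binning between the group's min and max counts (max always
grade 5; a single descriptor is trivially grade 5). The flavor network is
the bipartite compound–descriptor incidence graph; compounds without
descriptors remain isolated nodes.

## Antioxidant endpoints

Scavenging is 100·(1 − A_sample/A_0); values outside [0, 100] are passed
through with a warning rather than clipped, preserving assay pathology for
QC. IC50 defaults to bracketing linear interpolation on the concentration
axis (no functional form assumed); a 4PL least-squares fit is available
for smooth curves and reports the concentration where the fitted curve
crosses 50%. Replicates are pooled into one curve by default. FRAP inverts
an ordinary least-squares calibration line (absorbance vs mmol/L Fe²⁺) and
scales by extract volume over sample mass; absorbances outside the
calibrated span warn.

## Cross-block correlation

Correlations are computed on group-level quantities (default n = number of
groups) because antioxidant endpoints exist once per group; with n = 4,
coefficients of exactly ±1 are attainable and p-values are weak evidence,
so the output reports n with every pair. Pearson is the default; Spearman
is emitted alongside for heavy-tailed blocks such as ROAV. Hierarchical
clustering uses Ward linkage on Euclidean distances by default (average/
correlation optional) via deterministic agglomerative merges.

## Problem sizes and determinism

The shipped configuration exercises the full chain at the study scale
(16 injections × 200 features, 200 permutations) in seconds. Recovery
checks use the stated conditions: spiked effect 2 log2 units at n = 10 per
group; IC50 noise 1 percentage point over 8 concentrations; drift
amplitude 0.5 for the RSD-improvement check; permutation calibration over
100 label-independent datasets at n_perm = 50 (scaled down from 200, which
only refines the attainable p-grid). Every stochastic step takes an
explicit seed; identical seeds give bit-identical outputs.

## Known limitations

- With the minimum of 4 QC injections the LOESS fit nearly interpolates
  the QC points; QC RSD after correction is then a weak diagnostic.
- The permutation p-grid at n_perm = 50 makes the exact null rejection
  probability at the 0.05 level 2/51 ≈ 0.039 rather than 0.05.
- OPLS-DA is deliberately limited to two classes; multi-class questions go
  through PLS-DA or pairwise comparisons.
- The enrichment background is the detected universe; no pathway topology
  or impact scoring is attempted.
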