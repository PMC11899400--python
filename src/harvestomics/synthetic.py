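"""Synthetic study generator with recorded ground truth.

Emulates the data a harvest-time metabolomics study produces: a sample x
feature intensity table with pooled-QC injections and injection-order drift,
a volatile-compound odor table, four-parameter-logistic radical-scavenging
curves, and a toy superclass/pathway annotation. Every generator records the
truth it implanted (spiked effects, drift coefficients, true IC50, true OAV
ranking) so downstream stages can be tested by parameter recovery.

Design of the intensity model: baseline abundances are log-normal (log2
means drawn once per feature), differential features receive an additive
shift on the log2 scale in one designated group, and instrument drift is a
smooth strictly-positive multiplicative factor over injection order (linear
trend plus one low-frequency sinusoid) — the structure QC-based LOESS
correction is designed to remove. Pooled-QC injections carry the pooled mean
profile of all study samples, times drift, times measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .feature_table import QC_GROUP, FeatureTable

# Descriptor vocabulary emulating a flavor-descriptor database. Compounds
# drawn by the odor-table generator carry 1-4 of these labels.
DESCRIPTOR_VOCABULARY = [
    "sweet", "green", "floral", "woody", "fruity", "fresh", "herbal",
    "citrus", "fatty", "mushroom", "earthy", "spicy", "honey", "minty",
]

# Toy top-level chemical taxonomy buckets for annotation maps.
SUPERCLASS_NAMES = [
    "Lipids and lipid-like molecules",
    "Organic acids and derivatives",
    "Benzenoids",
    "Phenylpropanoids and polyketides",
    "Organoheterocyclic compounds",
    "Organic oxygen compounds",
    "Alkaloids and derivatives",
    "Nucleosides and analogues",
    "Organosulfur compounds",
    "Organic nitrogen compounds",
    "Hydrocarbons",
]


@dataclass
class SyntheticTruth:
    """Ground truth implanted by a generator run.

    Fields are populated by whichever generator produced the object; a
    feature-table run fills ``dam_features``/``drift_model``, an odor-table
    run fills ``oav_ranking``, an assay run fills ``true_ic50``.
    """

    dam_features: dict[str, float] = field(default_factory=dict)
    affected_group: str | None = None
    drift_model: dict[str, dict[str, float]] = field(default_factory=dict)
    true_ic50: dict[str, float] = field(default_factory=dict)
    oav_ranking: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise InvalidArgumentError("seed is required; reproducibility is mandatory")
    return np.random.default_rng(seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, shape))


def _qc_injection_orders(n_total: int, n_qc: int) -> np.ndarray:
    """QC slots at the start, the end, and evenly spread between."""
    if n_qc == 1:
        return np.array([1])
    pos = np.linspace(1, n_total, n_qc)
    orders = np.unique(np.round(pos).astype(int))
    # rounding collisions: fill forward into free slots
    while len(orders) < n_qc:
        free = np.setdiff1d(np.arange(1, n_total + 1), orders)
        orders = np.sort(np.append(orders, free[0]))
    return orders


def drift_factor(order: np.ndarray, coeffs: dict[str, float], n_total: int) -> np.ndarray:
    """Evaluate the smooth multiplicative drift model at injection orders."""
    x = (np.asarray(order, dtype=float) - 1) / max(n_total - 1, 1)
    d = 1.0 + coeffs["linear"] * (x - 0.5) + coeffs["sin"] * np.sin(2 * np.pi * x + coeffs["phase"])
    return np.maximum(d, 0.05)  # strictly positive by construction


def generate_feature_table(
    n_groups: int = 4,
    n_reps: int = 3,
    n_qc: int = 4,
    n_features: int = 200,
    n_dam: int = 60,
    effect_log2: float = 2.0,
    drift_amplitude: float = 0.3,
    noise_cv: float = 0.1,
    seed: int | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate the study's intensity table with pooled-QC injections.

    Defaults mirror the study design: 4 harvest groups x 3 replicates with
    4 pooled-QC injections. ``n_dam`` features are shifted by
    ``effect_log2`` (alternating sign) in the last group relative to all
    earlier groups; the truth records the signed per-feature effect.

    Returns the table and the implanted :class:`SyntheticTruth`.
    """
    rng = _require_seed(seed)
    for name, v in [("n_groups", n_groups), ("n_reps", n_reps), ("n_qc", n_qc),
                    ("n_features", n_features)]:
        if v < 1:
            raise InvalidArgumentError(f"{name} must be >= 1, got {v}")
    if n_dam > n_features:
        raise InvalidArgumentError("n_dam must not exceed n_features")
    if noise_cv < 0:
        raise InvalidArgumentError("noise_cv must be >= 0")

    n_samples = n_groups * n_reps
    n_total = n_samples + n_qc
    features = [f"F{i + 1:04d}" for i in range(n_features)]
    groups = [f"G{g + 1}" for g in range(n_groups)]

    # baseline log2 abundances, one per feature
    base_log2 = rng.uniform(10.0, 20.0, n_features)

    # signed spike-in effects in the last group
    dam_idx = rng.choice(n_features, size=n_dam, replace=False)
    signs = np.where(np.arange(n_dam) % 2 == 0, 1.0, -1.0)
    effects = np.zeros(n_features)
    effects[dam_idx] = effect_log2 * signs
    affected = groups[-1]

    # expected (noise-free, drift-free) intensity per group x feature
    mu_log2 = np.tile(base_log2, (n_groups, 1))
    mu_log2[-1, :] += effects
    expected = 2.0 ** mu_log2                        # groups x features
    pooled_profile = expected.mean(axis=0)           # QC = pooled mean profile

    # injection layout: QC at start/end/evenly between, samples shuffled
    qc_orders = _qc_injection_orders(n_total, n_qc)
    sample_orders = np.setdiff1d(np.arange(1, n_total + 1), qc_orders)
    sample_orders = rng.permutation(sample_orders)

    # per-feature smooth drift
    drift_coeffs = {
        f: {
            "linear": float(drift_amplitude * rng.uniform(-1, 1)),
            "sin": float(drift_amplitude * rng.uniform(-1, 1)),
            "phase": float(rng.uniform(0, 2 * np.pi)),
        }
        for f in features
    }
    coeff_mat = {k: np.array([drift_coeffs[f][k] for f in features]) for k in ("linear", "sin", "phase")}

    def drift_row(order: int) -> np.ndarray:
        x = (order - 1) / max(n_total - 1, 1)
        d = 1.0 + coeff_mat["linear"] * (x - 0.5) + coeff_mat["sin"] * np.sin(2 * np.pi * x + coeff_mat["phase"])
        return np.maximum(d, 0.05)

    rows, meta = [], []
    k = 0
    for g, group in enumerate(groups):
        for r in range(n_reps):
            order = int(sample_orders[k]); k += 1
            noise = _lognormal_noise(rng, noise_cv, n_features)
            rows.append(expected[g] * drift_row(order) * noise)
            meta.append((f"{group}_R{r + 1}", group, order))
    for q, order in enumerate(qc_orders):
        noise = _lognormal_noise(rng, noise_cv, n_features)
        rows.append(pooled_profile * drift_row(int(order)) * noise)
        meta.append((f"QC_{q + 1}", QC_GROUP, int(order)))

    samples = pd.DataFrame(meta, columns=["sample_id", "group", "injection_order"]).set_index("sample_id")
    values = pd.DataFrame(rows, index=samples.index, columns=features)
    table = FeatureTable(samples, values)

    truth = SyntheticTruth(
        dam_features={features[i]: float(effects[i]) for i in sorted(dam_idx)},
        affected_group=affected,
        drift_model=drift_coeffs,
    )
    return table, truth


def generate_odor_table(
    n_compounds: int = 40,
    n_groups: int = 4,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a volatile-compound table with known OAV ranking.

    Returns a long DataFrame with columns ``compound_id, group, peak_area,
    odor_threshold, descriptors`` (descriptors semicolon-joined) and the
    truth holding the per-group ordering of compounds by peak_area/threshold.
    """
    rng = _require_seed(seed)
    if n_compounds < 1:
        raise InvalidArgumentError("n_compounds must be >= 1")
    if n_groups < 1:
        raise InvalidArgumentError("n_groups must be >= 1")

    compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
    groups = [f"G{g + 1}" for g in range(n_groups)]
    # thresholds span orders of magnitude, as odor thresholds do
    thresholds = 10.0 ** rng.uniform(-2, 1, n_compounds)
    descriptors = {
        c: sorted(rng.choice(DESCRIPTOR_VOCABULARY, size=rng.integers(1, 5), replace=False))
        for c in compounds
    }

    records = []
    ranking: dict[str, list[str]] = {}
    for group in groups:
        areas = 10.0 ** rng.uniform(3, 7, n_compounds)
        oav = areas / thresholds
        ranking[group] = [compounds[i] for i in np.argsort(-oav, kind="stable")]
        for i, c in enumerate(compounds):
            records.append((c, group, float(areas[i]), float(thresholds[i]), ";".join(descriptors[c])))

    table = pd.DataFrame(records, columns=["compound_id", "group", "peak_area", "odor_threshold", "descriptors"])
    return table, SyntheticTruth(oav_ranking=ranking)


def generate_assay_curves(
    assay: str,
    true_ic50: float,
    hill_slope: float = 1.5,
    concentrations=None,
    noise_sd: float = 1.0,
    seed: int | None = None,
):
    """Simulate a radical-scavenging dose-response with known IC50.

    Scavenging follows a four-parameter logistic from 0 to 100% centred on
    ``true_ic50`` (mg/mL) with Gaussian noise (percentage points), clipped
    to [0, 100]. Absorbances are back-computed with a control of A0 = 1 so
    the assay module can recompute scavenging from raw readings.
    """
    from .assays import AssayCurve  # local import to avoid a cycle

    rng = _require_seed(seed)
    if concentrations is None:
        concentrations = np.geomspace(true_ic50 / 8, true_ic50 * 8, 8)
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any() or (np.diff(conc) <= 0).any():
        raise InvalidArgumentError("concentrations must be positive and strictly increasing")
    if not (conc[0] <= true_ic50 <= conc[-1]):
        raise InvalidArgumentError("true_ic50 must lie within the concentration span")
    if true_ic50 <= 0:
        raise InvalidArgumentError("true_ic50 must be positive")

    scavenging = 100.0 / (1.0 + (true_ic50 / conc) ** hill_slope)
    if noise_sd > 0:
        scavenging = scavenging + rng.normal(0, noise_sd, conc.shape)
    scavenging = np.clip(scavenging, 0.0, 100.0)

    a_0 = np.ones_like(conc)
    a_sample = (1.0 - scavenging / 100.0) * a_0
    return AssayCurve(assay=assay, concentrations=conc, a_sample=a_sample, a_0=a_0)


@dataclass
class AnnotationMap:
    """Feature annotation: one superclass per feature, overlapping pathways."""

    superclass: dict[str, str]
    pathways: dict[str, list[str]]

    def pathway_frame(self) -> pd.DataFrame:
        rows = [(p, f) for p, members in self.pathways.items() for f in members]
        return pd.DataFrame(rows, columns=["pathway_id", "feature_id"])

    def to_tsv(self, path) -> None:
        self.pathway_frame().to_csv(path, sep="\t", index=False)


def generate_annotation(
    feature_ids,
    n_superclasses: int = 6,
    n_pathways: int = 12,
    seed: int | None = None,
) -> AnnotationMap:
    """Assign every feature one superclass and build overlapping pathways."""
    rng = _require_seed(seed)
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise InvalidArgumentError("feature_ids must be non-empty")
    if n_superclasses < 1:
        raise InvalidArgumentError("n_superclasses must be >= 1")

    names = list(SUPERCLASS_NAMES)
    while len(names) < n_superclasses:
        names.append(f"Superclass {len(names) + 1}")
    names = names[:n_superclasses]
    superclass = {f: names[i] for f, i in zip(feature_ids, rng.integers(0, n_superclasses, len(feature_ids)))}

    pathways: dict[str, list[str]] = {}
    max_size = max(1, len(feature_ids) // 5)
    for p in range(n_pathways):
        size = int(rng.integers(1, max(2, max_size + 1)))
        members = rng.choice(feature_ids, size=size, replace=False)
        pathways[f"path{p + 1:02d}"] = sorted(members.tolist())
    return AnnotationMap(superclass=superclass, pathways=pathways)
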