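"""Shared configuration for the numbered analysis scripts.

All scripts regenerate their inputs deterministically from SEED via the
synthetic-data module, so each can be run standalone; outputs accumulate
under results/.
"""

from pathlib import Path

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = {
    "seed": SEED,
    "simulate": {"n_groups": 4, "n_reps": 3, "n_qc": 4, "n_features": 200,
                 "n_dam": 60, "effect_log2": 2.0, "drift_amplitude": 0.3,
                 "noise_cv": 0.1},
    "preprocess": {"span": 0.75, "max_rsd": 30.0},
    "model": {"n_components": 2, "n_perm": 200, "cv_folds": 7},
    "dam": {"vip_threshold": 1.0, "p_threshold": 0.05, "min_comparisons": 2},
    "odor": {"n_compounds": 40},
    "assays": {"true_ic50": {"DPPH": 1.2, "ABTS": 0.8}, "hill_slope": 1.5, "noise_sd": 1.0},
    "annotation": {"n_superclasses": 6, "n_pathways": 12},
}


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path


def simulate_study():
    """The study's intensity table + truth, regenerated from SEED."""
    from harvestomics import synthetic

    return synthetic.generate_feature_table(seed=SEED, **CONFIG["simulate"])


def preprocessed_study():
    """Drift-corrected, RSD-filtered table (raw scale, QC removed) + truth."""
    from harvestomics import preprocess

    table, truth = simulate_study()
    corrected, stats = preprocess.qc_loess_correct(table, span=CONFIG["preprocess"]["span"])
    filtered = preprocess.rsd_filter(corrected, max_rsd=CONFIG["preprocess"]["max_rsd"])
    return filtered.without_qc(), truth, stats
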