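"""Cross-block correlation, hierarchical clustering and the pipeline driver.

Correlations relate group-level quantities from different measurement
blocks (antioxidant endpoints, key-odorant scores, metabolite abundances).
Because antioxidant endpoints exist once per harvest group, the default
design correlates group means — few observations, so coefficients of
exactly 1 are possible and p-values are weak evidence; the table reports n
alongside r for that reason.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import assays, chemometrics, dam, enrichment, flavor, preprocess, synthetic
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


def correlation_matrix(blocks: dict[str, pd.DataFrame], method: str = "pearson") -> pd.DataFrame:
    """All between-block variable correlations in long format.

    Each block is a DataFrame over the same observations (rows, e.g. group
    means) with one column per variable. Constant variables are excluded
    with a warning; pairs with fewer than 3 shared observations are skipped.
    """
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    variables: list[tuple[str, str, pd.Series]] = []
    for block, frame in blocks.items():
        for col in frame.columns:
            s = frame[col].astype(float)
            if s.nunique(dropna=True) <= 1:
                warnings.warn(f"constant variable {block}:{col} excluded", stacklevel=2)
                continue
            variables.append((block, str(col), s))

    rows = []
    for (ba, va, sa), (bb, vb, sb) in itertools.combinations(variables, 2):
        if ba == bb:
            continue
        joined = pd.concat([sa, sb], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3:
            logger.info("pair %s:%s ~ %s:%s skipped (%d shared observations)", ba, va, bb, vb, n)
            continue
        r, p = corr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append({
            "block_a": ba, "variable_a": va, "block_b": bb, "variable_b": vb,
            "r": float(r), "p_value": float(p), "method": method, "n": n,
        })
    return pd.DataFrame(rows, columns=["block_a", "variable_a", "block_b", "variable_b",
                                       "r", "p_value", "method", "n"])


def cluster_heatmap(matrix: pd.DataFrame, linkage: str = "ward",
                    distance: str = "euclidean") -> dict:
    """Deterministic agglomerative clustering of rows and columns.

    Returns leaf orderings and merge (linkage) matrices ready for heatmap
    rendering; no plotting is done here.
    """
    if linkage not in ("ward", "average"):
        raise InvalidArgumentError(f"unknown linkage {linkage!r}")
    if distance not in ("euclidean", "correlation"):
        raise InvalidArgumentError(f"unknown distance {distance!r}")
    if linkage == "ward" and distance != "euclidean":
        raise InvalidArgumentError("ward linkage requires euclidean distance")

    def _cluster(data: np.ndarray, labels) -> tuple[list, np.ndarray | None]:
        if len(labels) < 2:
            return list(labels), None
        Z = hierarchy.linkage(pdist(data, metric=distance), method=linkage)
        order = hierarchy.leaves_list(Z)
        return [labels[i] for i in order], Z

    values = matrix.to_numpy(dtype=float)
    row_order, row_linkage = _cluster(values, list(matrix.index))
    col_order, col_linkage = _cluster(values.T, list(matrix.columns))
    return {
        "row_order": row_order, "col_order": col_order,
        "row_linkage": row_linkage, "col_linkage": col_linkage,
    }


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_groups": 4, "n_reps": 3, "n_qc": 4, "n_features": 200, "n_dam": 60,
        "effect_log2": 2.0, "drift_amplitude": 0.3, "noise_cv": 0.1,
    },
    "preprocess": {"span": 0.75, "max_rsd": 30.0},
    "model": {"n_components": 2, "n_perm": 200, "cv_folds": 7},
    "dam": {"vip_threshold": 1.0, "p_threshold": 0.05, "min_comparisons": 2},
    "odor": {"n_compounds": 40},
    "assays": {"true_ic50": {"DPPH": 1.2, "ABTS": 0.8}, "hill_slope": 1.5, "noise_sd": 1.0},
    "annotation": {"n_superclasses": 6, "n_pathways": 12},
}


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis chain on simulated data.

    simulate -> drift-correct/filter -> multivariate models -> pairwise DAM
    screen -> pathway enrichment -> ROAV/flavor -> antioxidant endpoints ->
    cross-block correlation. Returns a dict of in-memory results; when
    ``outdir`` is given, writes the tables (CSV/TSV), diagnostics (JSON) and
    a run log with the seed and parameters.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    results: dict = {"config": cfg}

    stage = "simulate"
    try:
        table, truth = synthetic.generate_feature_table(seed=seed, **cfg["simulate"])
        results["feature_table"], results["truth"] = table, truth

        stage = "preprocess"
        corrected, qc_stats = preprocess.qc_loess_correct(table, span=cfg["preprocess"]["span"])
        filtered = preprocess.rsd_filter(corrected, max_rsd=cfg["preprocess"]["max_rsd"])
        samples_only = filtered.without_qc()
        model_ready = preprocess.autoscale(preprocess.impute_and_log2(samples_only))
        results["qc_stats"] = qc_stats
        results["model_table"] = model_ready

        stage = "chemometrics"
        X = model_ready.values.to_numpy()
        labels = model_ready.samples["group"].tolist()
        n_comp = min(cfg["model"]["n_components"], len(labels) - 1, X.shape[1])
        results["pca"] = chemometrics.fit_pca(X, n_components=n_comp)
        plsda = chemometrics.fit_plsda(X, labels, n_components=n_comp)
        plsda.q2 = chemometrics.cross_validate_q2(
            X, labels, {"method": "plsda", "n_components": n_comp},
            k=cfg["model"]["cv_folds"], seed=seed,
        )
        plsda.permutation = chemometrics.permutation_test(
            X, labels, {"method": "plsda", "n_components": n_comp},
            n_perm=cfg["model"]["n_perm"], seed=seed, k=cfg["model"]["cv_folds"],
        )
        results["plsda"] = plsda

        stage = "dam_screen"
        groups = samples_only.groups()
        comparisons = {}
        for ga, gb in itertools.combinations(groups, 2):
            comparisons[f"{ga} vs {gb}"] = dam.pairwise_dam(
                samples_only, ga, gb,
                vip_threshold=cfg["dam"]["vip_threshold"],
                p_threshold=cfg["dam"]["p_threshold"],
            )
        upset, union_table = dam.integrate_comparisons(
            comparisons, min_comparisons=cfg["dam"]["min_comparisons"]
        )
        results["comparisons"] = comparisons
        results["upset"], results["dam_union"] = upset, union_table

        stage = "enrichment"
        annotation = synthetic.generate_annotation(
            samples_only.feature_ids, seed=seed, **cfg["annotation"]
        )
        results["annotation"] = annotation
        results["superclass_composition"] = dam.superclass_composition(
            union_table["feature_id"].tolist(), annotation
        )
        results["enrichment"] = enrichment.enrich_pathways(
            union_table["feature_id"].tolist(), samples_only.feature_ids, annotation.pathways
        )

        stage = "flavor"
        odor_table, odor_truth = synthetic.generate_odor_table(
            n_compounds=cfg["odor"]["n_compounds"], n_groups=len(groups), seed=seed
        )
        odor_table["group"] = odor_table["group"].map(dict(zip(sorted(odor_table["group"].unique()), groups)))
        roav_records = flavor.compute_roav(odor_table)
        keys = flavor.select_key_compounds(roav_records)
        descriptor_map = {
            c: d.split(";") for c, d in odor_table.drop_duplicates("compound_id")[
                ["compound_id", "descriptors"]].itertuples(index=False)
        }
        results["odor_truth"] = odor_truth
        results["roav"] = roav_records
        results["key_compounds"] = keys
        results["radar"] = flavor.descriptor_radar(keys, descriptor_map)
        graph, degrees = flavor.flavor_network(keys, descriptor_map)
        results["network"], results["network_degrees"] = graph, degrees

        stage = "assays"
        curves, ic50s = {}, {}
        for i, (assay_name, true_ic50) in enumerate(cfg["assays"]["true_ic50"].items()):
            curve = synthetic.generate_assay_curves(
                assay_name, true_ic50=true_ic50, hill_slope=cfg["assays"]["hill_slope"],
                noise_sd=cfg["assays"]["noise_sd"], seed=seed + i + 1,
            )
            curves[assay_name] = curve
            ic50s[assay_name] = assays.estimate_ic50(curve)
        results["assay_curves"], results["ic50"] = curves, ic50s

        stage = "correlate"
        group_means = samples_only.values.groupby(samples_only.samples["group"]).mean()
        dam_feats = union_table["feature_id"].head(10).tolist()
        roav_df = flavor.roav_frame(roav_records)
        roav_block = roav_df.pivot_table(index="group", columns="compound_id", values="roav")
        top_compounds = roav_block.mean().sort_values(ascending=False).head(5).index
        blocks = {
            "metabolite": group_means[dam_feats] if dam_feats else group_means.iloc[:, :5],
            "flavor": roav_block[top_compounds],
        }
        results["correlations"] = correlation_matrix(blocks, method="pearson")
        results["correlations_spearman"] = correlation_matrix(blocks, method="spearman")

        stage = "cluster"
        dam_cols = [f for f in union_table["feature_id"] if f in model_ready.values.columns]
        if dam_cols:
            results["heatmap"] = cluster_heatmap(model_ready.values[dam_cols])
    except Exception as exc:
        if outdir is not None:
            _write_outputs(results, Path(outdir))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = results.get("config", {})
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": cfg.get("seed"), "config": cfg}, fh, indent=2)
    if "feature_table" in results:
        results["feature_table"].to_csv(outdir / "feature_table.csv")
    if "truth" in results:
        results["truth"].to_json(outdir / "truth.json")
    if "dam_union" in results:
        results["dam_union"].to_csv(outdir / "dam_union.csv", index=False)
    if "upset" in results:
        with open(outdir / "upset.json", "w") as fh:
            json.dump(results["upset"], fh, indent=2)
    if "comparisons" in results:
        frames = [pd.DataFrame([r.__dict__ for r in recs]) for recs in results["comparisons"].values()]
        pd.concat(frames, ignore_index=True).to_csv(outdir / "dam_records.csv", index=False)
    if "enrichment" in results:
        enrichment.enrichment_frame(results["enrichment"]).to_csv(outdir / "enrichment.csv", index=False)
    if "superclass_composition" in results:
        results["superclass_composition"].to_csv(outdir / "superclass_composition.csv", index=False)
    if "roav" in results:
        flavor.roav_frame(results["roav"]).to_csv(outdir / "roav.csv", index=False)
    if "radar" in results:
        results["radar"].to_csv(outdir / "descriptor_radar.csv", index=False)
    if "network" in results:
        flavor.network_edge_list(results["network"]).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    if "ic50" in results:
        with open(outdir / "ic50.json", "w") as fh:
            json.dump({a: {"ic50": r.ic50, "method": r.method} for a, r in results["ic50"].items()}, fh, indent=2)
    if "correlations" in results:
        results["correlations"].to_csv(outdir / "correlations_pearson.csv", index=False)
        results["correlations_spearman"].to_csv(outdir / "correlations_spearman.csv", index=False)
    if "plsda" in results:
        m = results["plsda"]
        diag = {
            "r2x": m.r2x, "r2y": m.r2y, "q2": m.q2,
            "pca_explained_variance": results["pca"].explained_variance.tolist(),
            "permutation": {
                "n_perm": m.permutation.n_perm,
                "p_r2y": m.permutation.p_r2y, "p_q2": m.permutation.p_q2,
            } if m.permutation else None,
        }
        with open(outdir / "model_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)
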