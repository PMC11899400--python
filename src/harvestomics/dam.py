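"""Differential-metabolite screening and multi-comparison integration.

Two-step strategy: (1) per harvest-time pair, fit an OPLS-DA model on the
log2, autoscaled intensities and call a feature differential when its VIP
exceeds 1 AND a two-sided t-test on the log2 intensities gives p < 0.05;
(2) integrate the pairwise calls, prioritising features flagged in several
comparisons. Fold changes are reported as log2 of the raw group-mean ratio
(second group over first); Benjamini-Hochberg q-values are reported
alongside the raw p-values the screening rule uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chemometrics import fit_oplsda
from .errors import InvalidArgumentError
from .feature_table import FeatureTable
from .preprocess import autoscale, impute_and_log2

DEFAULT_VIP_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.05


@dataclass
class DAMRecord:
    feature_id: str
    comparison: str
    log2fc: float          # second group over first
    p_value: float
    q_value: float
    vip: float
    status: str            # "up" | "down" | "ns"


def _records_frame(records: list[DAMRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def pairwise_dam(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    vip_threshold: float = DEFAULT_VIP_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    equal_var: bool = True,
    n_orthogonal: int = 1,
) -> list[DAMRecord]:
    """Screen features differing between two groups.

    ``table`` holds drift-corrected, RSD-filtered raw intensities (QC rows
    ignored). "up" means higher in ``group_b``.
    """
    if table.transformed:
        raise InvalidArgumentError("pairwise_dam expects raw-scale intensities")
    for g in (group_a, group_b):
        if (table.samples["group"] == g).sum() < 2:
            raise InvalidArgumentError(f"group {g!r} absent or has < 2 replicates")

    mask = table.samples["group"].isin([group_a, group_b]).to_numpy()
    sub = FeatureTable(table.samples.loc[mask].copy(), table.values.loc[mask].copy())
    labels = sub.samples["group"].to_numpy()
    raw = sub.values

    # raw-scale fold change, log2 tests, autoscaled model for VIP
    log2_tab = impute_and_log2(sub)
    log2_vals = log2_tab.values
    scaled = autoscale(log2_tab)

    n_samples = len(labels)
    max_orth = max(0, min(n_orthogonal, n_samples - 3))
    model = fit_oplsda(scaled.values.to_numpy(), labels, n_orthogonal=max_orth)
    vip = pd.Series(model.vip, index=scaled.feature_ids)

    a_mask, b_mask = labels == group_a, labels == group_b
    mean_a = raw.loc[a_mask].mean(axis=0)
    mean_b = raw.loc[b_mask].mean(axis=0)

    records: list[DAMRecord] = []
    pvals: list[float] = []
    comparison = f"{group_a} vs {group_b}"
    for feat in log2_vals.columns:
        xa = log2_vals.loc[a_mask, feat].to_numpy()
        xb = log2_vals.loc[b_mask, feat].to_numpy()
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
        pvals.append(p)
        with np.errstate(divide="ignore"):
            fc = float(np.log2(mean_b[feat] / mean_a[feat])) if mean_a[feat] > 0 else np.inf
        records.append(DAMRecord(
            feature_id=feat, comparison=comparison, log2fc=fc,
            p_value=p, q_value=np.nan, vip=float(vip.get(feat, 0.0)), status="ns",
        ))

    qvals = multipletests(pvals, method="fdr_bh")[1]
    for rec, q in zip(records, qvals):
        rec.q_value = float(q)
        if rec.vip > vip_threshold and rec.p_value < p_threshold and rec.log2fc != 0:
            rec.status = "up" if rec.log2fc > 0 else "down"
    return records


def volcano_table(records: list[DAMRecord]) -> pd.DataFrame:
    """Plot-ready long table: log2FC, -log10 p and status per feature."""
    if not records:
        return pd.DataFrame(columns=["feature_id", "log2fc", "neg_log10_p", "status"])
    comparisons = {r.comparison for r in records}
    if len(comparisons) != 1:
        raise InvalidArgumentError("volcano_table expects records from a single comparison")
    frame = _records_frame(records)
    frame["neg_log10_p"] = -np.log10(frame["p_value"].clip(lower=np.finfo(float).tiny))
    frame.loc[frame["p_value"] == 1.0, "neg_log10_p"] = 0.0
    counts = frame["status"].value_counts().to_dict()
    frame.attrs["counts"] = {s: int(counts.get(s, 0)) for s in ("up", "down", "ns")}
    return frame[["feature_id", "log2fc", "neg_log10_p", "status"]]


def dam_set(records: list[DAMRecord]) -> set[str]:
    """Feature ids flagged up or down in one comparison."""
    return {r.feature_id for r in records if r.status != "ns"}


def integrate_comparisons(
    comparison_records: dict[str, list[DAMRecord]],
    min_comparisons: int = 2,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Upset-style intersection counts plus the prioritised DAM union.

    Returns ``(upset_counts, union_table)``: counts per *disjoint*
    membership class (keys like ``"A&B"``) and a table of all DAMs with the
    number of comparisons flagging each, sorted descending. Features in at
    least ``min_comparisons`` comparisons are marked consistent candidates.
    """
    if len(comparison_records) < 2:
        raise InvalidArgumentError("need >= 2 comparisons to integrate")
    sets = {name: dam_set(recs) for name, recs in comparison_records.items()}
    names = list(sets)

    upset: dict[str, int] = {}
    union = set().union(*sets.values())
    membership = {f: tuple(n for n in names if f in sets[n]) for f in union}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            count = sum(1 for m in membership.values() if m == combo)
            if count:
                upset["&".join(combo)] = count

    rows = [
        {"feature_id": f, "n_comparisons": len(m), "comparisons": ";".join(m),
         "consistent": len(m) >= min_comparisons}
        for f, m in membership.items()
    ]
    union_table = pd.DataFrame(rows, columns=["feature_id", "n_comparisons", "comparisons", "consistent"])
    union_table = union_table.sort_values(
        ["n_comparisons", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return upset, union_table


def superclass_composition(dam_union, annotation) -> pd.DataFrame:
    """Percentage of the DAM union per chemical superclass, sorted descending.

    Unannotated features fall into an "unclassified" bucket; percentages sum
    to 100 within rounding.
    """
    dam_union = list(dam_union)
    if not dam_union:
        return pd.DataFrame(columns=["superclass", "count", "percent"])
    classes = [annotation.superclass.get(f, "unclassified") for f in dam_union]
    counts = pd.Series(classes).value_counts()
    out = counts.rename_axis("superclass").reset_index(name="count")
    out["percent"] = out["count"] / out["count"].sum() * 100.0
    return out.sort_values(["count", "superclass"], ascending=[False, True]).reset_index(drop=True)
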