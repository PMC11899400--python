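"""Key-odorant scoring and flavor-profile summaries for volatile compounds.

The relative odor activity value (ROAV) rescales each compound's odor
activity value OAV = peak_area / odor_threshold so that the most
odor-active compound in scope (the reference) scores exactly 100; compounds
with ROAV > 1 are key flavor compounds. A literal mode reproducing the
product form ROAV_B = 100 * (Peak_B * T_B)/(Peak_A * T_A), with the
reference chosen as the compound with the smallest odor threshold, is kept
for comparison: that form does not bound scores by 100 and is not the
default.

Also here: Kovats-style retention-index interpolation against an n-alkane
ladder, detection-frequency radar grading of descriptors (grades 1-5, the
most frequent descriptor in a group always grade 5), and the bipartite
compound-descriptor network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidInputError, OutOfRangeError

DEFAULT_KEY_THRESHOLD = 1.0  # ROAV above this marks a key flavor compound
ODOR_COLUMNS = ["compound_id", "group", "peak_area", "odor_threshold", "descriptors"]


@dataclass
class RoavRecord:
    compound_id: str
    group: str
    oav: float
    roav: float
    is_reference: bool
    is_key: bool


def _validate_odor_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ODOR_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise InvalidInputError(f"odor table missing columns: {missing}")
    if (table["odor_threshold"] <= 0).any():
        raise InvalidInputError("odor thresholds must be strictly positive")
    if (table["peak_area"] < 0).any():
        raise InvalidInputError("peak areas must be non-negative")
    return table


def compute_roav(
    table: pd.DataFrame,
    mode: str = "default",
    reference_scope: str = "per_group",
    key_threshold: float = DEFAULT_KEY_THRESHOLD,
) -> list[RoavRecord]:
    """Score each compound's flavor contribution relative to the reference.

    Parameters
    ----------
    table:
        Long odor table with columns compound_id, group, peak_area,
        odor_threshold (and optionally descriptors).
    mode:
        "default" — OAV-ratio form, reference = compound maximising
        peak_area/odor_threshold in scope, all scores in (0, 100];
        "literal_eq3" — printed product form with the smallest-threshold
        compound as reference (scores unbounded; reference still 100).
    reference_scope:
        "per_group" selects a reference within each group; "global" uses
        one reference across the whole table.
    """
    if mode not in ("default", "literal_eq3"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if reference_scope not in ("per_group", "global"):
        raise InvalidArgumentError(f"unknown reference_scope {reference_scope!r}")
    table = _validate_odor_table(table)

    def reference_row(sub: pd.DataFrame) -> pd.Series:
        if mode == "default":
            return sub.loc[(sub["peak_area"] / sub["odor_threshold"]).idxmax()]
        return sub.loc[sub["odor_threshold"].idxmin()]

    records: list[RoavRecord] = []
    global_ref = reference_row(table) if reference_scope == "global" else None
    for group, sub in table.groupby("group", sort=False):
        if (sub["peak_area"] <= 0).all():
            warnings.warn(f"group {group!r} has no positive peak areas; skipped", stacklevel=2)
            continue
        ref = global_ref if global_ref is not None else reference_row(sub)
        for _, row in sub.iterrows():
            oav = row["peak_area"] / row["odor_threshold"]
            if mode == "default":
                ref_oav = ref["peak_area"] / ref["odor_threshold"]
                roav = 100.0 * (oav / ref_oav)  # ratio first: reference is exactly 100
            else:
                roav = 100.0 * (
                    (row["peak_area"] * row["odor_threshold"])
                    / (ref["peak_area"] * ref["odor_threshold"])
                )
            is_ref = row["compound_id"] == ref["compound_id"]
            records.append(RoavRecord(
                compound_id=row["compound_id"], group=group, oav=float(oav),
                roav=float(roav), is_reference=bool(is_ref),
                is_key=bool(roav > key_threshold),
            ))
    return records


def roav_frame(records: list[RoavRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def select_key_compounds(records: list[RoavRecord], threshold: float = DEFAULT_KEY_THRESHOLD) -> pd.DataFrame:
    """Rows with ROAV strictly above the threshold, plus per-group counts.

    The count table is attached as ``frame.attrs["key_counts"]``.
    """
    frame = roav_frame(records)
    if frame.empty:
        frame = pd.DataFrame(columns=["compound_id", "group", "oav", "roav", "is_reference", "is_key"])
    keys = frame[frame["roav"] > threshold].reset_index(drop=True)
    counts = keys.groupby("group", sort=False).size().to_dict() if not keys.empty else {}
    keys.attrs["key_counts"] = counts
    return keys


@dataclass
class RetentionIndexResult:
    rt: float
    lower_carbon: int
    upper_carbon: int
    ri: float


def retention_index(rt: float, alkane_rts: dict[int, float]) -> RetentionIndexResult:
    """Linear-interpolation retention index against an n-alkane ladder.

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)) for the bracketing
    alkanes C_n and C_{n+1}. No extrapolation outside the ladder.
    """
    if len(alkane_rts) < 2:
        raise InvalidArgumentError("need at least two alkane anchors")
    carbons = sorted(alkane_rts)
    times = [alkane_rts[c] for c in carbons]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise InvalidInputError("alkane retention times must increase with carbon number")
    if not times[0] <= rt <= times[-1]:
        raise OutOfRangeError(
            f"rt {rt} outside the alkane span [{times[0]}, {times[-1]}]"
        )
    i = int(np.searchsorted(times, rt, side="right")) - 1
    i = min(i, len(carbons) - 2)
    n, n1 = carbons[i], carbons[i + 1]
    frac = (rt - times[i]) / (times[i + 1] - times[i])
    return RetentionIndexResult(rt=rt, lower_carbon=n, upper_carbon=n1, ri=100.0 * (n + frac))


def _descriptors_of(compound: str, descriptor_map: dict[str, list[str]]) -> list[str]:
    desc = descriptor_map.get(compound)
    return list(desc) if desc else ["unknown"]


def descriptor_radar(key_compounds: pd.DataFrame, descriptor_map: dict[str, list[str]]) -> pd.DataFrame:
    """Detection-frequency grades (1-5) of descriptors among key compounds.

    Per group, each descriptor's count of carrying key compounds is mapped
    to a grade by equal-width binning between the group's min and max
    counts; the most frequent descriptor is always grade 5.
    """
    if key_compounds.empty:
        return pd.DataFrame(columns=["group", "descriptor", "count", "grade"])
    rows = []
    for group, sub in key_compounds.groupby("group", sort=False):
        counts: dict[str, int] = {}
        for comp in sub["compound_id"]:
            for d in _descriptors_of(comp, descriptor_map):
                counts[d] = counts.get(d, 0) + 1
        cmin, cmax = min(counts.values()), max(counts.values())
        for d, c in sorted(counts.items()):
            if cmax == cmin:
                grade = 5
            else:
                grade = 1 + int(np.floor(4.0 * (c - cmin) / (cmax - cmin)))
            rows.append({"group": group, "descriptor": d, "count": c, "grade": grade})
    return pd.DataFrame(rows)


def flavor_network(key_compounds: pd.DataFrame, descriptor_map: dict[str, list[str]]) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite compound-descriptor incidence network.

    Returns the graph (node attribute ``kind`` is "compound" or
    "descriptor") and its degree table. Compounds with no mapped
    descriptors remain as isolated nodes.
    """
    graph = nx.Graph()
    compounds = sorted(set(key_compounds["compound_id"])) if not key_compounds.empty else []
    for comp in compounds:
        graph.add_node(comp, kind="compound")
        for d in descriptor_map.get(comp, []):
            graph.add_node(d, kind="descriptor")
            graph.add_edge(comp, d)
    degrees = pd.DataFrame(
        [{"node": n, "kind": graph.nodes[n]["kind"], "degree": graph.degree[n]} for n in graph.nodes],
        columns=["node", "kind", "degree"],
    )
    return graph, degrees


def network_edge_list(graph: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(sorted(graph.edges), columns=["compound", "descriptor"])
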