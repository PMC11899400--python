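"""Pathway over-representation analysis of a DAM list.

One-sided hypergeometric upper-tail test per pathway (probability of
observing at least the seen number of DAM hits when drawing the DAM list
from the annotated background at random), Benjamini-Hochberg correction
across the tested pathways, and bubble-chart-ready output fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError


@dataclass
class EnrichmentRecord:
    pathway_id: str
    k: int            # DAM hits in the pathway
    m: int            # pathway size within the background
    n: int            # DAM list size
    N: int            # background size
    p_value: float
    q_value: float
    enrichment_ratio: float  # k over the expected hits n*m/N
    significant: bool = False


def enrich_pathways(
    dam_list,
    background,
    pathway_map: dict[str, list[str]],
    q_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation test for every pathway.

    Parameters
    ----------
    dam_list:
        Differential features (must be a subset of ``background``).
    background:
        The detected universe — all annotated features that survived
        preprocessing.
    pathway_map:
        pathway id -> member feature ids.
    q_threshold:
        Reported on the output records for downstream filtering; the full
        table is always returned, sorted by p-value.
    """
    background = set(background)
    dam = set(dam_list)
    if not background:
        raise InvalidArgumentError("background must be non-empty")
    if not dam <= background:
        raise InvalidArgumentError("dam_list must be a subset of background")

    N, n = len(background), len(dam)
    records: list[EnrichmentRecord] = []
    for pid, members in pathway_map.items():
        in_bg = set(members) & background
        m = len(in_bg)
        if m == 0:
            warnings.warn(f"pathway {pid!r} has no background members; skipped", stacklevel=2)
            continue
        k = len(in_bg & dam)
        # P[X >= k] for X ~ Hypergeom(N, m, n)
        p = float(hypergeom.sf(k - 1, N, m, n))
        expected = n * m / N
        records.append(EnrichmentRecord(
            pathway_id=pid, k=k, m=m, n=n, N=N,
            p_value=min(p, 1.0), q_value=float("nan"),
            enrichment_ratio=k / expected if expected > 0 else float("nan"),
        ))

    if records:
        qvals = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, qvals):
            r.q_value = float(q)
            r.significant = r.q_value <= q_threshold
        records.sort(key=lambda r: (r.p_value, r.pathway_id))
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Bubble-chart-ready table (ratio for x, hits for size, q for colour)."""
    cols = ["pathway_id", "k", "m", "n", "N", "p_value", "q_value", "enrichment_ratio", "significant"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
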