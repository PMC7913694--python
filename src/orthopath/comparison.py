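"""Jaccard-index agreement of expressed pathway members across organisms.

For one pathway and tissue, each organism contributes the set of pathway
OGs it expresses there; the Jaccard index (JI) between the reference and a
model organism is intersection over union of those two sets.  OGs without
expression information in either organism appear in neither set and cannot
affect the index.  An empty union (0/0) carries no evidence and is
propagated as missing, never coerced to 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import call_pivots
from .expression import ExpressionCalls

__all__ = ["jaccard", "compare_all", "summarize_ji"]


def jaccard(a: Iterable, b: Iterable) -> float | None:
    """|a∩b| / |a∪b|; ``None`` when both sets are empty (undefined)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


def compare_all(
    og_calls: Mapping[str, ExpressionCalls],
    pathway_ogs: Mapping[str, frozenset[str]],
    tissues: Sequence[str],
    reference: str,
    models: Sequence[str],
) -> pd.DataFrame:
    """Per pathway×tissue: JI of expressed OGs vs each model organism.

    Columns: pathway, tissue, ji_<model> (NaN when undefined),
    n_union_<model> (size of the pairwise expressed union),
    n_expressed_union (expressed OGs in the tissue, union over all
    organisms) and n_expressed_ref — the two candidate gate quantities for
    the downstream PCA filter.
    """
    pivots = {org: call_pivots(og_calls[org], tissues) for org in (reference, *models)}
    rows = []
    for name in sorted(pathway_ogs):
        ogs = sorted(pathway_ogs[name])
        per_org_expressed: dict[str, dict[str, frozenset]] = {}
        for org, (info, expr) in pivots.items():
            present = info.index.intersection(ogs)
            sub_info, sub_expr = info.loc[present], expr.loc[present]
            per_org_expressed[org] = {
                t: frozenset(sub_expr.index[sub_info[t] & sub_expr[t]])
                for t in tissues
            }
        for tissue in tissues:
            ref_set = per_org_expressed[reference][tissue]
            row: dict[str, object] = {"pathway": name, "tissue": tissue}
            all_union: set = set(ref_set)
            for m in models:
                mset = per_org_expressed[m][tissue]
                all_union |= mset
                ji = jaccard(ref_set, mset)
                row[f"ji_{m}"] = np.nan if ji is None else ji
                row[f"n_union_{m}"] = len(ref_set | mset)
            row["n_expressed_union"] = len(all_union)
            row["n_expressed_ref"] = len(ref_set)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_ji(
    records: pd.DataFrame, models: Sequence[str]
) -> tuple[dict[str, float], pd.DataFrame]:
    """Arithmetic means over *defined* JIs only.

    Returns the overall per-pair mean (NaN where a pair has no defined JI)
    and a per-tissue per-pair mean frame.
    """
    overall = {m: float(records[f"ji_{m}"].mean()) for m in models}
    per_tissue = (
        records.groupby("tissue", sort=True)[[f"ji_{m}" for m in models]]
        .mean()
        .reset_index()
    )
    return overall, per_tissue
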