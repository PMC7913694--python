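"""Pathway-level expression profiles and breadth summaries.

For each (pathway, tissue, organism) the expression fraction is the number
of pathway OGs called expressed divided by the number of pathway OGs with
any expression information in that tissue; OGs without a score there are
excluded from the denominator, not treated as unexpressed.  A pathway is
*expressed* in a tissue/organism when that fraction reaches the configured
threshold (default 0.85, inclusive).

Pathways whose informative members (over the whole tissue panel) number
fewer than the minimum in any organism are excluded up front, mirroring the
minimum-size rule applied at transfer time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionCalls

__all__ = ["profile_pathways", "summarize_expression_breadth", "call_pivots"]


class ActivityError(ValueError):
    pass


def call_pivots(
    calls: ExpressionCalls, tissues: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean entity×tissue pivots (has-information, is-expressed)."""
    df = calls.calls[calls.calls["tissue"].isin(tissues)]
    info = (
        df.assign(v=True)
        .pivot_table(index="entity", columns="tissue", values="v",
                     aggfunc="any", fill_value=False)
        .reindex(columns=list(tissues), fill_value=False)
        .astype(bool)
    )
    expr = (
        df.pivot_table(index="entity", columns="tissue", values="expressed",
                       aggfunc="any", fill_value=False)
        .reindex(columns=list(tissues), fill_value=False)
        .reindex(index=info.index, fill_value=False)
        .astype(bool)
    )
    return info, expr


def profile_pathways(
    pathway_ogs: Mapping[str, frozenset[str]],
    og_calls: Mapping[str, ExpressionCalls],
    tissues: Sequence[str],
    min_info: int = 5,
    expressed_fraction: float = 0.85,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(pathway, tissue, organism) profile frame plus excluded pathways.

    Output columns: pathway, tissue, organism, n_info, n_expressed,
    fraction, expressed.  ``fraction`` is NaN (and ``expressed`` False)
    where no member OG has information in the tissue.
    """
    if not tissues:
        raise ActivityError("empty tissue list")
    pivots = {org: call_pivots(c, tissues) for org, c in og_calls.items()}

    excluded: list[str] = []
    retained: list[str] = []
    for name in sorted(pathway_ogs):
        ogs = pathway_ogs[name]
        ok = True
        for org, (info, _) in pivots.items():
            present = info.index.intersection(sorted(ogs))
            n_informative = int(info.loc[present].any(axis=1).sum())
            if n_informative < min_info:
                ok = False
                break
        (retained if ok else excluded).append(name)

    rows = []
    for name in retained:
        ogs = sorted(pathway_ogs[name])
        for org, (info, expr) in pivots.items():
            present = info.index.intersection(ogs)
            n_info = info.loc[present].sum(axis=0)
            n_expr = (info.loc[present] & expr.loc[present]).sum(axis=0)
            for tissue in tissues:
                ni, ne = int(n_info[tissue]), int(n_expr[tissue])
                frac = ne / ni if ni else float("nan")
                rows.append(
                    {
                        "pathway": name,
                        "tissue": tissue,
                        "organism": org,
                        "n_info": ni,
                        "n_expressed": ne,
                        "fraction": frac,
                        "expressed": bool(ni and frac >= expressed_fraction),
                    }
                )
    profiles = pd.DataFrame(
        rows,
        columns=["pathway", "tissue", "organism", "n_info", "n_expressed",
                 "fraction", "expressed"],
    )
    return profiles, excluded


def summarize_expression_breadth(
    profiles: pd.DataFrame, broad_tissue_count: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression breadth per pathway and expressed-pathway counts per tissue.

    Returns ``(breadth, tissue_counts)``:

    * ``breadth`` — one row per pathway×organism with the number of tissues
      in which the pathway is expressed, plus ``broadly_expressed``: true
      when the pathway reaches ``broad_tissue_count`` tissues in *every*
      organism (house-keeping-like behaviour).
    * ``tissue_counts`` — number of expressed pathways per tissue×organism.
    """
    breadth = (
        profiles.groupby(["pathway", "organism"], sort=True)["expressed"]
        .sum()
        .rename("n_tissues_expressed")
        .reset_index()
    )
    min_breadth = breadth.groupby("pathway")["n_tissues_expressed"].min()
    breadth["broadly_expressed"] = (
        breadth["pathway"].map(min_breadth) >= broad_tissue_count
    )
    tissue_counts = (
        profiles.groupby(["tissue", "organism"], sort=True)["expressed"]
        .sum()
        .rename("n_pathways_expressed")
        .reset_index()
    )
    return breadth, tissue_counts
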