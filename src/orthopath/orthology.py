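"""Orthologous-group bookkeeping.

Orthologous groups (OGs) are the bridge for every cross-species mapping in
this package: a group collects the genes of several organisms that descend
from a common ancestral gene.  Real catalogues (eggNOG-style tables at the
mammalian level) have imperfect coverage — a group may lack an organism
entirely, or contain several within-organism paralogs — so downstream
analyses must be able to restrict the table to groups with a particular
coverage pattern before comparing organisms.

Coverage patterns are expressed as :class:`OGFilter` modes over a named
organism subset:

``any_at_least_one``
    at least one of the named organisms has >= 1 gene in the group
``each_at_least_one``
    every named organism has >= 1 gene (the "common groups" of a comparison)
``any_exactly_one``
    at least one named organism has exactly 1 gene
``each_exactly_one``
    every named organism has exactly 1 gene (strict 1-to-1 orthologs)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["OrthologyTable", "OGFilter", "filter_groups", "map_genes_to_groups"]

_MODES = ("any_at_least_one", "each_at_least_one", "any_exactly_one", "each_exactly_one")


class OrthologyError(ValueError):
    """Raised for structurally invalid orthology tables or filters."""


class OrthologyTable:
    """Immutable membership table: one row per (group, organism, gene).

    Gene identifiers are namespaced by organism: the same string in two
    organisms denotes two distinct genes.  Within one organism a gene may
    belong to at most one group.
    """

    def __init__(self, memberships: pd.DataFrame):
        required = ["og_id", "organism", "gene_id"]
        missing = [c for c in required if c not in memberships.columns]
        if missing:
            raise OrthologyError(f"membership table lacks columns: {missing}")
        df = (
            memberships[required]
            .astype(str)
            .drop_duplicates()
            .sort_values(required, kind="mergesort")
            .reset_index(drop=True)
        )
        if df.empty:
            raise OrthologyError("orthology table has no memberships")
        dup = df.duplicated(subset=["organism", "gene_id"], keep=False)
        if dup.any():
            bad = df.loc[dup, ["organism", "gene_id"]].drop_duplicates().head(5)
            raise OrthologyError(
                "gene(s) assigned to more than one group: "
                + ", ".join(f"{o}/{g}" for o, g in bad.itertuples(index=False))
            )
        self._df = df
        self._counts: pd.DataFrame | None = None
        self._gene_to_group: dict[tuple[str, str], str] | None = None

    # -- accessors ---------------------------------------------------------

    @property
    def memberships(self) -> pd.DataFrame:
        """Canonical (sorted, deduplicated) membership frame."""
        return self._df.copy()

    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(self._df["organism"].unique())

    @property
    def group_ids(self) -> list[str]:
        return sorted(self._df["og_id"].unique())

    @property
    def n_groups(self) -> int:
        return self._df["og_id"].nunique()

    @property
    def counts(self) -> pd.DataFrame:
        """Group x organism gene counts (0 where an organism is absent)."""
        if self._counts is None:
            self._counts = (
                self._df.groupby(["og_id", "organism"], sort=True)
                .size()
                .unstack(fill_value=0)
            )
        return self._counts

    def genes_of(self, organism: str) -> frozenset[str]:
        return frozenset(self._df.loc[self._df["organism"] == organism, "gene_id"])

    def members(self, og_id: str, organism: str | None = None) -> frozenset[str]:
        sel = self._df["og_id"] == og_id
        if organism is not None:
            sel &= self._df["organism"] == organism
        return frozenset(self._df.loc[sel, "gene_id"])

    def gene_group(self, organism: str, gene: str) -> str | None:
        if self._gene_to_group is None:
            self._gene_to_group = {
                (o, g): og
                for og, o, g in self._df.itertuples(index=False)
            }
        return self._gene_to_group.get((organism, gene))

    def subset(self, og_ids: Iterable[str]) -> "OrthologyTable":
        keep = set(og_ids)
        return OrthologyTable(self._df[self._df["og_id"].isin(keep)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OrthologyTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"OrthologyTable({self.n_groups} groups, {len(self._df)} memberships, "
            f"organisms={sorted(self.organisms)})"
        )


@dataclass(frozen=True)
class OGFilter:
    """Coverage-class filter over a named organism subset."""

    mode: str
    organisms: tuple[str, ...]

    def __post_init__(self):
        if self.mode not in _MODES:
            raise OrthologyError(f"unknown filter mode {self.mode!r}; valid: {_MODES}")
        if not self.organisms:
            raise OrthologyError("filter organism set is empty")
        object.__setattr__(self, "organisms", tuple(self.organisms))


def filter_groups(table: OrthologyTable, og_filter: OGFilter) -> OrthologyTable:
    """Restrict ``table`` to the groups whose coverage satisfies the filter.

    Coverage is evaluated only over ``og_filter.organisms``; memberships of
    other organisms in the surviving groups are kept unchanged.  Idempotent.
    """
    unknown = set(og_filter.organisms) - table.organisms
    if unknown:
        raise OrthologyError(f"organisms not in table: {sorted(unknown)}")
    counts = table.counts.reindex(columns=list(og_filter.organisms), fill_value=0)
    if og_filter.mode == "any_at_least_one":
        mask = (counts >= 1).any(axis=1)
    elif og_filter.mode == "each_at_least_one":
        mask = (counts >= 1).all(axis=1)
    elif og_filter.mode == "any_exactly_one":
        mask = (counts == 1).any(axis=1)
    else:  # each_exactly_one
        mask = (counts == 1).all(axis=1)
    kept = counts.index[mask]
    if len(kept) == 0:
        raise OrthologyError(
            f"no group satisfies {og_filter.mode} over {og_filter.organisms}"
        )
    return table.subset(kept)


def map_genes_to_groups(
    table: OrthologyTable, genes: Iterable[str], organism: str
) -> tuple[dict[str, str], frozenset[str]]:
    """Map ``organism`` genes to their group ids.

    Returns ``(mapping, unmapped)``: genes absent from every group are not
    silently dropped but reported in ``unmapped``.  The mapping is a function
    (one group per gene) by table invariant.
    """
    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    for g in genes:
        og = table.gene_group(organism, g)
        if og is None:
            unmapped.add(g)
        else:
            mapping[g] = og
    return mapping, frozenset(unmapped)
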