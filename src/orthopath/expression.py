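"""Tissue-expression calibration and binary expression calls.

Gene–tissue association strength comes in as calibrated confidence scores
(TISSUES-style), whose ranges differ substantially between organisms due to
study bias and data volume.  Absolute cutoffs are therefore meaningless
across organisms; instead an organism- and tissue-specific cutoff is placed
at a configured empirical percentile of that organism×tissue score
distribution (default: the median), which makes the expressed/not-expressed
call rank-based and invariant under any monotone rescaling of one
organism×tissue's scores.

The percentile is the *lower nearest-rank* value: the smallest observed
score s such that at least p% of the scores are <= s.  No interpolation is
performed, so the cutoff is always an observed score and the definition is
reproducible exactly across languages and library versions.

A gene is called expressed in a tissue iff its score is strictly greater
than the cutoff ("above" the cutoff).  With heavy ties at the cutoff this
can call fewer than (100-p)% of the genes — intended behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import OrthologyTable

__all__ = [
    "ExpressionTable",
    "CutoffTable",
    "ExpressionCalls",
    "nearest_rank_percentile",
    "filter_tissues",
    "compute_cutoffs",
    "call_expressed",
    "collapse_to_ogs",
]

CHANNELS = ("experimental", "integrated")


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionTable:
    """Per-organism gene×tissue confidence scores plus tissue metadata.

    ``records`` columns: gene_id, tissue, score, channel — at most one row
    per (gene, tissue, channel), all scores finite.  ``tissue_meta`` maps a
    tissue label to the number of experimental datasets supporting it.
    The ``gene_id`` column may also carry OG identifiers after
    :func:`collapse_to_ogs`; the schema is unchanged.
    """

    organism: str
    records: pd.DataFrame
    tissue_meta: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        required = ["gene_id", "tissue", "score", "channel"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ExpressionError(f"expression table lacks columns: {missing}")
        df = self.records[required].copy()
        df["score"] = pd.to_numeric(df["score"], errors="raise")
        if not np.isfinite(df["score"]).all():
            raise ExpressionError("non-finite confidence score")
        bad_channel = set(df["channel"]) - set(CHANNELS)
        if bad_channel:
            raise ExpressionError(f"unknown evidence channel(s): {sorted(bad_channel)}")
        df = df.drop_duplicates().sort_values(required[:3], kind="mergesort")
        dup = df.duplicated(subset=["gene_id", "tissue", "channel"], keep=False)
        if dup.any():
            bad = df.loc[dup, ["gene_id", "tissue", "channel"]].head(3)
            raise ExpressionError(
                "conflicting scores for "
                + "; ".join(map(str, bad.itertuples(index=False, name=None)))
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))
        object.__setattr__(self, "tissue_meta", dict(self.tissue_meta))

    def channel(self, channel: str) -> pd.DataFrame:
        if channel not in CHANNELS:
            raise ExpressionError(f"unknown channel {channel!r}")
        return self.records[self.records["channel"] == channel]

    @property
    def tissues(self) -> frozenset[str]:
        return frozenset(self.records["tissue"].unique())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionTable)
            and self.organism == other.organism
            and self.records.equals(other.records)
            and dict(self.tissue_meta) == dict(other.tissue_meta)
        )


@dataclass(frozen=True)
class CutoffTable:
    """(organism, tissue) -> score cutoff at a fixed percentile."""

    percentile: float
    entries: Mapping[tuple[str, str], float]
    n_scores: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def cutoff(self, organism: str, tissue: str) -> float:
        key = (organism, tissue)
        if key not in self.entries:
            raise ExpressionError(f"no cutoff for organism={organism}, tissue={tissue}")
        return self.entries[key]


@dataclass(frozen=True)
class ExpressionCalls:
    """Binary expressed/not-expressed calls at gene or OG granularity.

    ``calls`` columns: entity, tissue, score, expressed.  A call exists only
    where a score exists — absence of a record means "no information", which
    is distinct from "not expressed".
    """

    organism: str
    calls: pd.DataFrame

    def expressed_entities(self, tissue: str) -> frozenset[str]:
        sel = (self.calls["tissue"] == tissue) & self.calls["expressed"]
        return frozenset(self.calls.loc[sel, "entity"])

    def informative_entities(self, tissue: str) -> frozenset[str]:
        return frozenset(self.calls.loc[self.calls["tissue"] == tissue, "entity"])


def nearest_rank_percentile(scores: Sequence[float] | np.ndarray, percentile: float) -> float:
    """Lower nearest-rank percentile: smallest s with #(scores <= s) >= p%·n."""
    if not 0 < percentile < 100:
        raise ExpressionError(f"percentile must be in (0,100), got {percentile}")
    arr = np.sort(np.asarray(scores, dtype=float))
    n = arr.size
    if n == 0:
        raise ExpressionError("cannot take a percentile of zero scores")
    k = math.ceil(percentile / 100.0 * n)
    return float(arr[k - 1])


def filter_tissues(
    tables: Mapping[str, ExpressionTable], min_datasets: int
) -> list[str]:
    """Tissues supported by >= ``min_datasets`` datasets in *every* organism."""
    tissue_sets = []
    for org, tab in tables.items():
        if not tab.tissue_meta:
            raise ExpressionError(f"no tissue metadata for organism {org!r}")
        tissue_sets.append(
            {t for t, n in tab.tissue_meta.items() if n >= min_datasets}
        )
    common = set.intersection(*tissue_sets) if tissue_sets else set()
    return sorted(common)


def compute_cutoffs(
    table: ExpressionTable,
    tissues: Sequence[str],
    percentile: float,
    channel: str = "experimental",
) -> CutoffTable:
    """Per-tissue nearest-rank cutoffs from one organism's score distribution.

    Cutoffs are calibrated on *gene-level* scores (before any collapsing to
    orthologous groups), one cutoff per organism×tissue.
    """
    df = table.channel(channel)
    entries: dict[tuple[str, str], float] = {}
    n_scores: dict[tuple[str, str], int] = {}
    for tissue in tissues:
        scores = df.loc[df["tissue"] == tissue, "score"].to_numpy()
        if scores.size == 0:
            raise ExpressionError(
                f"no {channel} scores for organism={table.organism}, tissue={tissue}"
            )
        entries[(table.organism, tissue)] = nearest_rank_percentile(scores, percentile)
        n_scores[(table.organism, tissue)] = int(scores.size)
    return CutoffTable(percentile=percentile, entries=entries, n_scores=n_scores)


def call_expressed(
    table: ExpressionTable, cutoffs: CutoffTable, channel: str = "experimental"
) -> ExpressionCalls:
    """Call each scored (entity, tissue) expressed iff score > cutoff."""
    df = table.channel(channel)
    tissues = sorted(df["tissue"].unique())
    missing = [t for t in tissues if (table.organism, t) not in cutoffs.entries]
    if missing:
        raise ExpressionError(
            f"missing cutoff for organism={table.organism}, tissues={missing}"
        )
    cut = df["tissue"].map(lambda t: cutoffs.entries[(table.organism, t)])
    out = pd.DataFrame(
        {
            "entity": df["gene_id"].to_numpy(),
            "tissue": df["tissue"].to_numpy(),
            "score": df["score"].to_numpy(),
            "expressed": (df["score"].to_numpy() > cut.to_numpy()),
        }
    ).sort_values(["entity", "tissue"], kind="mergesort").reset_index(drop=True)
    return ExpressionCalls(organism=table.organism, calls=out)


def collapse_to_ogs(
    table: ExpressionTable, orthology: OrthologyTable
) -> ExpressionTable:
    """Collapse gene-level scores to OG level by the max over member genes.

    Within-organism paralogs in one group are represented by their highest
    confidence score.  Genes not assigned to any group are dropped; an OG
    has expression information in a tissue iff at least one of its member
    genes has a score there (no record otherwise — missing is not zero).
    """
    members = orthology.memberships
    members = members[members["organism"] == table.organism][["og_id", "gene_id"]]
    merged = table.records.merge(members, on="gene_id", how="inner")
    collapsed = (
        merged.groupby(["og_id", "tissue", "channel"], sort=True, as_index=False)["score"]
        .max()
        .rename(columns={"og_id": "gene_id"})
    )
    return ExpressionTable(
        organism=table.organism,
        records=collapsed[["gene_id", "tissue", "score", "channel"]],
        tissue_meta=table.tissue_meta,
    )
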