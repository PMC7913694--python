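"""Orthology-mediated overlap of gene-level annotations between organisms.

Two organisms' annotation sets become comparable by projecting each
annotated gene onto its orthologous group: GO-style term annotations turn
into (term, OG) pairs, and gene–gene interactions into unordered OG pairs.
The overlap is the size of the intersection of the projected sets.  Genes
without a group are dropped; paralogs of one organism in the same group
collapse onto the same projected item, so it is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .orthology import OrthologyTable

__all__ = ["AnnotationTable", "term_overlap", "interaction_overlap",
           "DEFAULT_EVIDENCE_GROUPS"]

# GO evidence codes grouped by provenance; the grouping is configurable,
# this is the conventional four-way split.
DEFAULT_EVIDENCE_GROUPS: dict[str, str] = {
    **{c: "Experimental" for c in
       ("EXP", "HAD", "HEP", "HMP", "IDA", "IEP", "IPI", "IGI", "IMP")},
    **{c: "Author statement" for c in ("TAS", "NAS")},
    **{c: "Inferred" for c in ("IKR", "IBA", "ISS", "RCA", "ISO", "ISA", "ISM", "IC")},
    "IEA": "Electronic",
}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationTable:
    """Per-organism annotation pairs.

    ``kind="term"``: ``pairs`` has columns (gene_id, term) and optionally
    evidence_code.  ``kind="interaction"``: columns (gene1, gene2,
    confidence); pairs are unordered and normalized so gene1 <= gene2.
    """

    organism: str
    kind: str
    pairs: pd.DataFrame

    def __post_init__(self):
        if self.kind not in ("term", "interaction"):
            raise AnnotationError(f"unknown annotation kind {self.kind!r}")
        df = self.pairs.copy()
        if self.kind == "term":
            need = {"gene_id", "term"}
            if need - set(df.columns):
                raise AnnotationError("term table needs columns gene_id, term")
        else:
            need = {"gene1", "gene2", "confidence"}
            if need - set(df.columns):
                raise AnnotationError(
                    "interaction table needs columns gene1, gene2, confidence"
                )
            lo = df[["gene1", "gene2"]].min(axis=1)
            hi = df[["gene1", "gene2"]].max(axis=1)
            df["gene1"], df["gene2"] = lo, hi
        object.__setattr__(self, "pairs", df.drop_duplicates().reset_index(drop=True))


def _og_of(table: OrthologyTable, organism: str) -> pd.DataFrame:
    m = table.memberships
    return m.loc[m["organism"] == organism, ["og_id", "gene_id"]]


def term_overlap(
    a: AnnotationTable, b: AnnotationTable, table: OrthologyTable
) -> int:
    """Number of (term, OG) pairs annotated in both organisms."""
    if a.kind != "term" or b.kind != "term":
        raise AnnotationError("term_overlap requires two term-type tables")
    sets = []
    for t in (a, b):
        og = _og_of(table, t.organism)
        merged = t.pairs.merge(og, on="gene_id", how="inner")
        sets.append(set(zip(merged["term"], merged["og_id"])))
    return len(sets[0] & sets[1])


def interaction_overlap(
    a: AnnotationTable,
    b: AnnotationTable,
    table: OrthologyTable,
    min_conf: float = 0.7,
    include_self_pairs: bool = True,
) -> int:
    """Unordered OG pairs interacting (above ``min_conf``) in both organisms.

    An interaction whose two genes fall in the same group yields a self
    OG pair {og, og}; it is counted once, and only if ``include_self_pairs``.
    """
    if a.kind != "interaction" or b.kind != "interaction":
        raise AnnotationError("interaction_overlap requires interaction-type tables")
    sets = []
    for t in (a, b):
        og = _og_of(table, t.organism)
        df = t.pairs[t.pairs["confidence"] >= min_conf]
        df = (
            df.merge(og.rename(columns={"gene_id": "gene1", "og_id": "og1"}), on="gene1")
            .merge(og.rename(columns={"gene_id": "gene2", "og_id": "og2"}), on="gene2")
        )
        pairs = {tuple(sorted(p)) for p in zip(df["og1"], df["og2"])}
        if not include_self_pairs:
            pairs = {p for p in pairs if p[0] != p[1]}
        sets.append(pairs)
    return len(sets[0] & sets[1])
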