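"""Orthology-based pathway transfer and transferability.

A reference-organism pathway (a human KEGG-style gene set) is transferred to
a model organism by mapping each reference gene to its orthologous group,
turning the pathway–gene association into a pathway–OG association.  The
*transferability* to a target is then the fraction of those member groups
that contain at least one gene of the target organism.  Two reference
paralogs falling in one group count once — the denominator is the number of
distinct groups hit, and reference genes with no group are excluded from the
denominator (but counted and reported).

Joint transfer to several targets at once only credits groups covered by
*every* target, so joint transferability is never above any pairwise value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import PathwaySet
from .orthology import OrthologyTable, map_genes_to_groups

__all__ = ["TransferredPathway", "transfer_pathway", "transfer_all", "pathway_og_sets"]


class TransferError(ValueError):
    pass


@dataclass(frozen=True)
class TransferredPathway:
    pathway: str
    targets: tuple[str, ...]
    og_members: frozenset[str]
    transferred_ogs: frozenset[str]
    n_unmapped_reference_genes: int

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.transferred_ogs <= self.og_members:
            raise TransferError("transferred groups must be member groups")

    @property
    def transferability(self) -> float:
        if not self.og_members:
            return float("nan")
        return len(self.transferred_ogs) / len(self.og_members)

    @property
    def organism(self) -> str:
        return "+".join(self.targets)


def transfer_pathway(
    pathway_genes: Iterable[str],
    table: OrthologyTable,
    targets: str | Sequence[str],
    reference: str,
    pathway: str = "",
) -> TransferredPathway:
    """Transfer one reference gene set to one target (or jointly to several).

    ``og_members`` are the distinct groups hit by mapped reference genes;
    ``transferred_ogs`` the subset containing at least one gene of every
    named target.
    """
    if isinstance(targets, str):
        targets = (targets,)
    targets = tuple(targets)
    unknown = set(targets) - table.organisms
    if unknown:
        raise TransferError(f"target organism(s) not in table: {sorted(unknown)}")
    mapping, unmapped = map_genes_to_groups(table, pathway_genes, reference)
    og_members = frozenset(mapping.values())
    if og_members:
        counts = table.counts.loc[sorted(og_members)]
        covered = pd.Series(True, index=counts.index)
        for t in targets:
            covered &= (counts[t] >= 1) if t in counts.columns else False
        transferred = frozenset(counts.index[covered])
    else:
        transferred = frozenset()
    return TransferredPathway(
        pathway=pathway,
        targets=targets,
        og_members=og_members,
        transferred_ogs=transferred,
        n_unmapped_reference_genes=len(unmapped),
    )


def transfer_all(
    pathways: PathwaySet,
    table: OrthologyTable,
    targets: Sequence[str],
    reference: str,
    min_pathway_genes: int = 5,
) -> tuple[list[TransferredPathway], list[str]]:
    """Transfer every pathway pairwise to each target and jointly to all.

    A pathway is excluded (and listed) when its distinct mapped groups, or
    its transferred groups for *any* single target, number fewer than
    ``min_pathway_genes`` — one shared pathway set underlies all
    comparisons, so failing in one organism drops the pathway everywhere.
    """
    if len(pathways) == 0:
        raise TransferError("empty pathway set")
    results: list[TransferredPathway] = []
    excluded: list[str] = []
    for name in pathways:
        per_target = [
            transfer_pathway(pathways[name], table, t, reference, pathway=name)
            for t in targets
        ]
        too_small = any(
            len(tp.og_members) < min_pathway_genes
            or len(tp.transferred_ogs) < min_pathway_genes
            for tp in per_target
        )
        if too_small:
            excluded.append(name)
            continue
        results.extend(per_target)
        if len(targets) > 1:
            results.append(
                transfer_pathway(pathways[name], table, tuple(targets), reference,
                                 pathway=name)
            )
    return results, excluded


def pathway_og_sets(
    pathways: PathwaySet,
    table: OrthologyTable,
    reference: str,
    names: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Pathway -> member OG set under ``table`` (typically the all-organism
    restricted table), the entity universe for expression comparison."""
    out: dict[str, frozenset[str]] = {}
    for name in (names if names is not None else pathways):
        mapping, _ = map_genes_to_groups(table, pathways[name], reference)
        out[name] = frozenset(mapping.values())
    return out


def transfer_frame(results: Sequence[TransferredPathway]) -> pd.DataFrame:
    """Tabular view: pathway, organism, n_ogs, n_transferred, transferability, n_unmapped."""
    return pd.DataFrame(
        [
            {
                "pathway": tp.pathway,
                "organism": tp.organism,
                "n_ogs": len(tp.og_members),
                "n_transferred": len(tp.transferred_ogs),
                "transferability": tp.transferability,
                "n_unmapped": tp.n_unmapped_reference_genes,
            }
            for tp in results
        ]
    ).sort_values(["pathway", "organism"], kind="mergesort").reset_index(drop=True)
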