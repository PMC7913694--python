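"""Readers, writers and run configuration.

All downstream modules consume only the typed objects produced here:
:class:`~orthopath.orthology.OrthologyTable` from an eggNOG-style membership
TSV, :class:`PathwaySet` from a standard GMT gene-set file, and
:class:`~orthopath.expression.ExpressionTable` from a TISSUES-style score
TSV plus a per-tissue dataset-count TSV.

Every writer produces a deterministic byte stream (fixed column order, fixed
row sort, fixed float formatting) and round-trips losslessly through the
matching reader.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression import ExpressionTable
from .orthology import OrthologyTable

__all__ = [
    "Config",
    "PathwaySet",
    "read_og_table",
    "write_og_table",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "write_table",
    "read_table",
]

FLOAT_FORMAT = "%.12g"


class DataIOError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Config:
    """Run configuration; defaults reproduce the published parameterization.

    expression_percentile
        percentile of the organism×tissue score distribution used as the
        expressed/not-expressed cutoff; the median by default.
    expressed_pathway_fraction
        a pathway counts as expressed in a tissue when at least this
        fraction of its informative orthologous members is above the cutoff.
    min_pathway_genes
        pathways with fewer orthologous members than this (in any compared
        organism) are dropped, both at transfer and at profiling time.
    min_expressed_genes_for_pca
        pathway–tissue pairs enter the PCA only with at least this many
        expressed members in the tissue.
    min_tissue_datasets
        tissues must be covered by at least this many experimental datasets
        in every organism to enter the panel.
    top_n
        number of center-most-distant pathway–tissue pairs assigned to
        organism groups.
    """

    reference_organism: str = "human"
    model_organisms: tuple[str, ...] = ("mouse", "rat", "pig")
    expression_percentile: float = 50.0
    expressed_pathway_fraction: float = 0.85
    min_pathway_genes: int = 5
    min_expressed_genes_for_pca: int = 5
    min_tissue_datasets: int = 2
    top_n: int = 200
    rng_seed: int = 0
    score_channel: str = "experimental"
    broad_tissue_count: int = 3
    pca_scale: bool = False
    pca_expressed_scope: str = "union"  # or "reference"

    def __post_init__(self):
        object.__setattr__(self, "model_organisms", tuple(self.model_organisms))
        if not self.model_organisms:
            raise DataIOError("model_organisms must be non-empty")
        if self.reference_organism in self.model_organisms:
            raise DataIOError("reference organism cannot also be a model organism")
        if len(set(self.model_organisms)) != len(self.model_organisms):
            raise DataIOError("duplicate model organism")
        if not 0 < self.expression_percentile < 100:
            raise DataIOError("expression_percentile must be in (0,100)")
        if not 0 < self.expressed_pathway_fraction <= 1:
            raise DataIOError("expressed_pathway_fraction must be in (0,1]")
        for name in ("min_pathway_genes", "min_expressed_genes_for_pca",
                     "min_tissue_datasets"):
            if int(getattr(self, name)) < 1:
                raise DataIOError(f"{name} must be >= 1")
        if self.top_n < 1:
            raise DataIOError("top_n must be >= 1")
        if self.score_channel not in ("experimental", "integrated"):
            raise DataIOError(f"unknown score_channel {self.score_channel!r}")
        if self.pca_expressed_scope not in ("union", "reference"):
            raise DataIOError("pca_expressed_scope must be 'union' or 'reference'")

    @property
    def organisms(self) -> tuple[str, ...]:
        return (self.reference_organism, *self.model_organisms)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Parse a flat ``key = value`` text file (# starts a comment)."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataIOError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise DataIOError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(key: str, value: str) -> object:
    if key == "model_organisms":
        return tuple(s.strip() for s in value.split(",") if s.strip())
    if key in ("expression_percentile", "expressed_pathway_fraction"):
        return float(value)
    if key in ("min_pathway_genes", "min_expressed_genes_for_pca",
               "min_tissue_datasets", "top_n", "rng_seed", "broad_tissue_count"):
        return int(value)
    if key == "pca_scale":
        return value.lower() in ("1", "true", "yes")
    return value


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwaySet:
    """Named gene sets for the reference organism.

    ``pathways`` maps a unique pathway name to a frozen set of gene ids;
    ``descriptions`` keeps the GMT description column for round-tripping.
    """

    pathways: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "pathways",
                           {k: frozenset(v) for k, v in self.pathways.items()})
        object.__setattr__(self, "descriptions", dict(self.descriptions))

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def __iter__(self):
        return iter(sorted(self.pathways))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwaySet) and dict(self.pathways) == dict(other.pathways)


def read_gmt(path: str | Path) -> PathwaySet:
    """Read a standard GMT file: name <TAB> description <TAB> gene ids...

    Duplicate genes within a pathway are collapsed; a duplicated pathway
    name or a malformed line (fewer than three fields, or an empty gene
    field) is an error.
    """
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataIOError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in pathways:
            raise DataIOError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        if any(g == "" for g in genes):
            raise DataIOError(f"{path}:{lineno}: empty gene field in {name!r}")
        pathways[name] = frozenset(genes)
        descriptions[name] = desc
    if not pathways:
        raise DataIOError(f"{path}: empty GMT file")
    return PathwaySet(pathways=pathways, descriptions=descriptions)


def write_gmt(pathway_set: PathwaySet, path: str | Path) -> None:
    lines = []
    for name in sorted(pathway_set.pathways):
        desc = pathway_set.descriptions.get(name, "")
        genes = sorted(pathway_set.pathways[name])
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# orthology tables
# ---------------------------------------------------------------------------

def read_og_table(path: str | Path) -> OrthologyTable:
    """Read an eggNOG-style membership TSV with columns og_id, organism, gene_id."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataIOError(f"{path}: empty orthology file") from None
    missing = {"og_id", "organism", "gene_id"} - set(df.columns)
    if missing:
        raise DataIOError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise DataIOError(f"{path}: orthology file has no rows")
    return OrthologyTable(df)


def write_og_table(table: OrthologyTable, path: str | Path) -> None:
    write_table(table.memberships, path)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, organism: str, meta_path: str | Path | None = None
) -> ExpressionTable:
    """Read a TISSUES-style score TSV (gene_id, tissue, score, channel).

    ``meta_path`` points to a companion TSV of (tissue, n_datasets).  Exact
    duplicate rows are collapsed; the same (gene, tissue, channel) with
    conflicting scores, or a non-numeric score, is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "channel": str})
    missing = {"gene_id", "tissue", "score", "channel"} - set(df.columns)
    if missing:
        raise DataIOError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise DataIOError(f"{path}: non-numeric score ({exc})") from None
    meta: dict[str, int] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype={"tissue": str})
        if {"tissue", "n_datasets"} - set(mdf.columns):
            raise DataIOError(f"{meta_path}: expected columns tissue, n_datasets")
        meta = dict(zip(mdf["tissue"], mdf["n_datasets"].astype(int)))
    return ExpressionTable(organism=organism, records=df, tissue_meta=meta)


def write_expression(
    table: ExpressionTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    write_table(table.records, path)
    if meta_path is not None:
        meta = pd.DataFrame(
            sorted(table.tissue_meta.items()), columns=["tissue", "n_datasets"]
        )
        write_table(meta, meta_path)


# ---------------------------------------------------------------------------
# generic deterministic TSV output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, sort: bool = True) -> None:
    """Write a stage output TSV deterministically.

    Rows are sorted by all columns (left to right) and floats rendered with
    a fixed repr so two runs on identical inputs are byte-identical.
    """
    out = df.copy()
    if sort and len(out):
        out = out.sort_values(list(out.columns), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
               lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
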