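"""End-to-end orchestration: filter → transfer → calibrate → call → profile
→ compare → ordinate → assign, with deterministic outputs and a manifest.

The pipeline consumes either a directory of input files (in the formats of
:mod:`orthopath.io`) or an in-memory :class:`~orthopath.simulate.SyntheticData`
bundle, and produces a :class:`PipelineResult` whose ``write`` method emits
every stage table as a deterministic TSV plus a JSON manifest (config
snapshot, input digests, package version, seed).  Identical inputs, config
and seed give byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activity import profile_pathways, summarize_expression_breadth
from .assignment import (
    PCAResult,
    ZeroVarianceError,
    assign_groups,
    group_summary,
    rank_by_center_distance,
    run_pca,
)
from .comparison import compare_all, jaccard, summarize_ji
from .expression import (
    CutoffTable,
    ExpressionCalls,
    call_expressed,
    collapse_to_ogs,
    compute_cutoffs,
    filter_tissues,
)
from .io import Config, PathwaySet, read_expression, read_gmt, read_og_table, write_table
from .orthology import OGFilter, OrthologyTable, filter_groups
from .simulate import SyntheticData
from .transfer import pathway_og_sets, transfer_all, transfer_frame

__all__ = ["PipelineResult", "StageError", "run_all", "sweep", "linked_fraction"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial results."""

    def __init__(self, stage: str, cause: Exception, partial: "PipelineResult | None" = None):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


@dataclass
class PipelineResult:
    config: Config
    tissues: list[str] | None = None
    transfer: pd.DataFrame | None = None
    transfer_excluded: list[str] | None = None
    cutoffs: Mapping[str, CutoffTable] | None = None
    og_calls: Mapping[str, ExpressionCalls] | None = None
    pathway_ogs: Mapping[str, frozenset[str]] | None = None
    profiles: pd.DataFrame | None = None
    profile_excluded: list[str] | None = None
    breadth: pd.DataFrame | None = None
    tissue_counts: pd.DataFrame | None = None
    ji: pd.DataFrame | None = None
    ji_overall: Mapping[str, float] | None = None
    ji_per_tissue: pd.DataFrame | None = None
    pca: PCAResult | None = None
    assignments: pd.DataFrame | None = None
    summaries: Mapping[str, pd.DataFrame] | None = None
    input_digests: Mapping[str, str] | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        models = cfg.model_organisms
        if self.tissues is not None:
            write_table(pd.DataFrame({"tissue": self.tissues}), out / "tissues.tsv")
        if self.transfer is not None:
            write_table(self.transfer, out / "transferability.tsv")
            write_table(
                pd.DataFrame({"pathway": sorted(self.transfer_excluded or [])}),
                out / "excluded_transfer.tsv",
            )
        if self.cutoffs is not None:
            rows = [
                {
                    "organism": org,
                    "tissue": t,
                    "percentile": ct.percentile,
                    "cutoff": c,
                    "n_scores": ct.n_scores.get((org, t), 0),
                }
                for org, ct in self.cutoffs.items()
                for (org_, t), c in sorted(ct.entries.items())
            ]
            write_table(pd.DataFrame(rows), out / "cutoffs.tsv")
        if self.og_calls is not None:
            for org, calls in self.og_calls.items():
                write_table(
                    calls.calls, out / f"og_calls_{org.replace(' ', '_')}.tsv"
                )
        if self.profiles is not None:
            write_table(self.profiles, out / "profiles.tsv")
            write_table(
                pd.DataFrame({"pathway": sorted(self.profile_excluded or [])}),
                out / "excluded_profiles.tsv",
            )
        if self.breadth is not None:
            write_table(self.breadth, out / "breadth.tsv")
            write_table(self.tissue_counts, out / "tissue_pathway_counts.tsv")
        if self.ji is not None:
            cols = ["pathway", "tissue"] + [f"ji_{m}" for m in models]
            write_table(self.ji[cols + ["n_expressed_union"]], out / "jaccard.tsv")
            write_table(self.ji_per_tissue, out / "jaccard_per_tissue.tsv")
        if self.pca is not None:
            k = self.pca.n_components
            summary = pd.DataFrame(
                {
                    "pc": [f"PC{i + 1}" for i in range(k)],
                    "explained_variance": self.pca.explained_variance,
                    "explained_variance_ratio": self.pca.explained_variance_ratio,
                }
            )
            write_table(summary, out / "pca_summary.tsv", sort=False)
            write_table(
                self.pca.loadings.reset_index(names="organism"),
                out / "pca_loadings.tsv",
                sort=False,
            )
        if self.assignments is not None:
            write_table(self.assignments, out / "assignments.tsv")
        if self.summaries is not None:
            write_table(self.summaries["groups"], out / "group_summary.tsv")
            write_table(self.summaries["per_tissue"], out / "group_per_tissue.tsv")
            write_table(
                self.summaries["single_organism_pathways"],
                out / "single_organism_pathways.tsv",
            )
        manifest = {
            "config": {
                f.name: (list(v) if isinstance(v := getattr(cfg, f.name), tuple) else v)
                for f in dataclasses.fields(cfg)
            },
            "inputs": dict(self.input_digests or {}),
            "version": __version__,
            "seed": cfg.rng_seed,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(
    config: Config, data: "SyntheticData | Mapping[str, str | Path]"
) -> tuple[OrthologyTable, PathwaySet, dict, dict[str, str]]:
    if isinstance(data, SyntheticData):
        return data.orthology, data.pathways, dict(data.expression), {}
    paths = {k: Path(v) for k, v in data.items()}
    digests = {k: _sha256(p) for k, p in sorted(paths.items())}
    orthology = read_og_table(paths["og_table"])
    pathways = read_gmt(paths["pathways"])
    expression = {}
    for org in config.organisms:
        key = f"expression_{org}"
        meta_key = f"tissue_meta_{org}"
        expression[org] = read_expression(
            paths[key], org, paths.get(meta_key)
        )
    return orthology, pathways, expression, digests


def run_all(
    config: Config,
    data: "SyntheticData | Mapping[str, str | Path]",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage in order; abort with a stage-named error.

    On failure the raised :class:`StageError` carries the results of the
    stages already completed in ``partial`` (useful for the degenerate
    zero-variance case, where everything up to the Jaccard table is valid).
    """
    res = PipelineResult(config=config)
    stage = "load"
    try:
        orthology, pathways, expression, digests = _load_inputs(config, data)
        res.input_digests = digests

        stage = "tissue_filter"
        res.tissues = filter_tissues(expression, config.min_tissue_datasets)
        if not res.tissues:
            raise ValueError("no tissue passes the dataset-count filter in all organisms")

        stage = "transfer"
        results, excluded = transfer_all(
            pathways,
            orthology,
            config.model_organisms,
            config.reference_organism,
            config.min_pathway_genes,
        )
        res.transfer = transfer_frame(results)
        res.transfer_excluded = excluded

        stage = "orthology_restriction"
        orth_all = filter_groups(
            orthology, OGFilter("each_at_least_one", config.organisms)
        )
        retained = [p for p in pathways if p not in set(excluded)]
        res.pathway_ogs = pathway_og_sets(
            pathways, orth_all, config.reference_organism, retained
        )

        stage = "cutoffs"
        res.cutoffs = {
            org: compute_cutoffs(
                expression[org], res.tissues, config.expression_percentile,
                config.score_channel,
            )
            for org in config.organisms
        }

        stage = "calls"
        res.og_calls = {
            org: call_expressed(
                collapse_to_ogs(expression[org], orth_all),
                res.cutoffs[org],
                config.score_channel,
            )
            for org in config.organisms
        }

        stage = "profiles"
        res.profiles, res.profile_excluded = profile_pathways(
            res.pathway_ogs,
            res.og_calls,
            res.tissues,
            min_info=config.min_pathway_genes,
            expressed_fraction=config.expressed_pathway_fraction,
        )
        res.breadth, res.tissue_counts = summarize_expression_breadth(
            res.profiles, config.broad_tissue_count
        )

        stage = "jaccard"
        comparable = {
            p: s for p, s in res.pathway_ogs.items()
            if p not in set(res.profile_excluded)
        }
        res.ji = compare_all(
            res.og_calls, comparable, res.tissues,
            config.reference_organism, config.model_organisms,
        )
        res.ji_overall, res.ji_per_tissue = summarize_ji(
            res.ji, config.model_organisms
        )

        stage = "pca"
        res.pca = run_pca(
            res.ji,
            config.model_organisms,
            config.min_expressed_genes_for_pca,
            scale=config.pca_scale,
            expressed_scope=config.pca_expressed_scope,
        )

        stage = "assignment"
        ranked = rank_by_center_distance(res.pca)
        res.assignments = assign_groups(ranked, res.pca, config.top_n)
        res.summaries = group_summary(
            res.assignments, res.ji, config.model_organisms
        )
    except Exception as exc:
        raise StageError(stage, exc, partial=res) from exc

    if out_dir is not None:
        res.write(out_dir)
    return res


def linked_fraction(percentile: float) -> float:
    """Expressed-pathway fraction linked to the expression percentile.

    The stricter the gene-level cutoff (higher percentile, fewer genes
    expressed), the lower the pathway-level fraction must sit: 0.85 at or
    below the median, decreasing linearly to 0.75 at the 75th percentile.
    """
    if percentile <= 50:
        return 0.85
    return max(0.5, 0.85 - 0.4 * (percentile - 50) / 100)


def sweep(
    config: Config,
    grid: Mapping[str, Sequence],
    data: "SyntheticData | Mapping[str, str | Path]",
    link_fraction: bool = True,
) -> dict[str, pd.DataFrame]:
    """Robustness sweep over a config-parameter grid.

    Runs the full pipeline at every grid point and reports, per point, the
    per-group assignment counts, and pairwise Jaccard overlap of the top-N
    assigned (pathway, tissue) sets between points.  When the grid varies
    ``expression_percentile`` and ``expressed_pathway_fraction`` is not
    itself part of the grid, the pathway fraction follows
    :func:`linked_fraction` unless ``link_fraction=False``.
    """
    keys = list(grid)
    points = list(itertools.product(*(grid[k] for k in keys)))
    rows = []
    assigned_sets: list[frozenset] = []
    for values in points:
        overrides = dict(zip(keys, values))
        if (
            link_fraction
            and "expression_percentile" in overrides
            and "expressed_pathway_fraction" not in overrides
        ):
            overrides["expressed_pathway_fraction"] = linked_fraction(
                overrides["expression_percentile"]
            )
        cfg = dataclasses.replace(config, **overrides)
        result = run_all(cfg, data)
        assigned = result.assignments[result.assignments["group"] != "unassigned"]
        assigned_sets.append(
            frozenset(zip(assigned["pathway"], assigned["tissue"]))
        )
        row = {k: v for k, v in zip(keys, values)}
        for _, grow in result.summaries["groups"].iterrows():
            row[f"n_{grow['group'].replace(' & ', '_')}"] = grow["n_pairs"]
        rows.append(row)
    overlaps = []
    for i, j in itertools.combinations(range(len(points)), 2):
        ov = jaccard(assigned_sets[i], assigned_sets[j])
        overlaps.append(
            {
                "point_a": i,
                "point_b": j,
                "overlap": float("nan") if ov is None else ov,
            }
        )
    return {
        "points": pd.DataFrame(rows),
        "overlap": pd.DataFrame(overlaps, columns=["point_a", "point_b", "overlap"]),
    }
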