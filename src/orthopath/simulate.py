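"""Seeded multi-organism synthetic data with planted ground truth.

The generator emulates the statistical structure of the pipeline's inputs:

* an orthologous-group table with imperfect coverage — a tunable fraction of
  strict 1-to-1 groups, per-organism missingness, and within-organism
  paralogs;
* reference-organism pathways of realistic sizes drawn over the groups;
* per-organism gene×tissue confidence scores whose *ranges differ between
  organisms* (a per-organism scale factor), which is exactly the
  heterogeneity that motivates rank-based percentile cutoffs;
* a conserved true expression layer: each (group, tissue) is expressed with
  probability ``q_expressed`` identically in all organisms, then perturbed
  by an independent per-organism flip rate ``epsilon``;
* planted organism-specific divergences: for selected (pathway, tissue)
  pairs, a fraction of the pathway's groups has its true state flipped in
  one organism or one organism pair only — the signal the downstream
  PCA assignment should recover;
* house-keeping pathways whose groups are expressed almost everywhere.

Divergence is planted on the true-state layer, not on scores, so percentile
calibration, thresholding, Jaccard comparison and PCA are all exercised
end-to-end.  Everything is driven by one ``numpy`` Generator; a fixed seed
gives byte-identical output files.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .expression import ExpressionTable
from .io import PathwaySet, write_expression, write_gmt, write_og_table, write_table
from .orthology import OrthologyTable

__all__ = ["SimulationConfig", "SyntheticData", "GroundTruth", "generate",
           "evaluate_recovery"]

TISSUE_PANEL = ("heart", "kidney", "liver", "lung", "muscle", "nervous system", "spleen")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    Four mammals with a human reference, 5000 orthologous groups, 200
    pathways of 10–40 members over a 7-tissue panel; baseline expression
    probability 0.5, background flip rate 0.05, and 20 planted divergent
    pathway–tissue pairs per divergence class with 40% of the pathway's
    groups flipped.  Score locations/scales are organism-specific (score
    ranges differing by an order of magnitude across organisms, as observed
    in calibrated tissue-expression databases).
    """

    organisms: tuple[str, ...] = ("human", "mouse", "rat", "pig")
    n_ogs: int = 5000
    p_one_to_one: float = 0.35
    p_missing: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.08, "mouse": 0.08, "rat": 0.18, "pig": 0.15}
    )
    p_paralog: float = 0.2
    n_unassigned_genes: int = 200
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (40, 120)
    tissues: tuple[str, ...] = TISSUE_PANEL
    n_datasets: Mapping[str, int] = field(
        default_factory=lambda: {"human": 4, "mouse": 4, "rat": 3, "pig": 3}
    )
    q_expressed: float = 0.5
    epsilon: float = 0.05
    p_missing_score: float = 0.05
    loc_unexpressed: float = 1.0
    loc_expressed: float = 3.0
    score_sd: float = 0.35
    score_scale: Mapping[str, float] = field(
        default_factory=lambda: {"human": 1.0, "mouse": 2.0, "rat": 0.5, "pig": 4.0}
    )
    tie_rate: float = 0.0
    n_housekeeping: int = 8
    q_housekeeping: float = 0.95
    n_planted_per_class: int = 20
    flip_fraction: float = 0.4
    # explicit planting overrides the per-class scheme: entries are
    # (pathway name, tissue, divergent organisms joined by "+", flip fraction)
    planted_divergences: tuple[tuple[str, str, str, float], ...] | None = None
    channels: tuple[str, ...] = ("experimental", "integrated")
    n_go_terms: int = 60
    n_annotated_ogs: int = 400
    n_interactions: int = 200
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_one_to_one", "p_paralog", "q_expressed", "epsilon",
                     "p_missing_score", "tie_rate", "q_housekeeping",
                     "flip_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        for org in self.organisms:
            if not 0 <= self.p_missing.get(org, 0.0) <= 1:
                raise SimulationError(f"p_missing[{org}] out of [0,1]")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise SimulationError("invalid pathway_size_range")
        if hi > self.n_ogs:
            raise SimulationError("pathway size exceeds number of groups")
        if len(self.organisms) < 2:
            raise SimulationError("need a reference and at least one model organism")

    @property
    def reference(self) -> str:
        return self.organisms[0]

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(self.organisms[1:])

    def divergence_classes(self) -> list[tuple[str, ...]]:
        """Single organisms then unordered pairs, in model-organism order."""
        singles = [(m,) for m in self.models]
        pairs = [tuple(p) for p in itertools.combinations(self.models, 2)]
        return singles + pairs

    def expected_group(self, divergent: tuple[str, ...]) -> str:
        """Group an assignment should recover for a planted divergence."""
        rest = [m for m in self.models if m not in divergent]
        return " & ".join(rest)


@dataclass(frozen=True)
class GroundTruth:
    og_counts: pd.DataFrame                 # og_id x organism gene counts
    true_expression: Mapping[str, pd.DataFrame]  # organism -> og x tissue bool
    planted: pd.DataFrame                   # pathway, tissue, divergent, expected_group
    housekeeping: tuple[str, ...]
    pathway_ogs: Mapping[str, tuple[str, ...]]


@dataclass(frozen=True)
class SyntheticData:
    config: SimulationConfig
    orthology: OrthologyTable
    pathways: PathwaySet
    expression: Mapping[str, ExpressionTable]
    go_annotations: Mapping[str, AnnotationTable]
    interactions: Mapping[str, AnnotationTable]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit every input file in the pipeline's own formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["og_table"] = out / "og_table.tsv"
        write_og_table(self.orthology, paths["og_table"])
        paths["pathways"] = out / "pathways.gmt"
        write_gmt(self.pathways, paths["pathways"])
        for org, tab in self.expression.items():
            p = out / f"expression_{org.replace(' ', '_')}.tsv"
            m = out / f"tissue_meta_{org.replace(' ', '_')}.tsv"
            write_expression(tab, p, m)
            paths[f"expression_{org}"] = p
            paths[f"tissue_meta_{org}"] = m
        for org, tab in self.go_annotations.items():
            p = out / f"go_{org.replace(' ', '_')}.tsv"
            write_table(tab.pairs, p)
            paths[f"go_{org}"] = p
        for org, tab in self.interactions.items():
            p = out / f"ppi_{org.replace(' ', '_')}.tsv"
            write_table(tab.pairs, p)
            paths[f"ppi_{org}"] = p
        paths["planted"] = out / "ground_truth_planted.tsv"
        write_table(self.truth.planted, paths["planted"])
        return paths


def _og_id(i: int) -> str:
    return f"OG{i:05d}"


def generate(config: SimulationConfig) -> SyntheticData:
    """Generate one synthetic study; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.rng_seed)
    orgs = list(config.organisms)
    n_org, n_ogs = len(orgs), config.n_ogs
    tissues = list(config.tissues)
    n_tis = len(tissues)

    # ----- orthologous-group coverage ------------------------------------
    one2one = rng.random(n_ogs) < config.p_one_to_one
    present = np.empty((n_ogs, n_org), dtype=bool)
    for j, org in enumerate(orgs):
        present[:, j] = rng.random(n_ogs) >= config.p_missing.get(org, 0.0)
    paralog = rng.random((n_ogs, n_org)) < config.p_paralog
    counts = np.where(
        one2one[:, None], 1, present.astype(int) * (1 + paralog.astype(int))
    )
    empty = counts.sum(axis=1) == 0
    if empty.any():  # every group must have at least one member
        forced = rng.integers(0, n_org, size=int(empty.sum()))
        counts[np.flatnonzero(empty), forced] = 1

    og_ids = np.array([_og_id(i) for i in range(n_ogs)])
    rows_og, rows_org, rows_gene = [], [], []
    for j, org in enumerate(orgs):
        for copy, suffix in ((1, "a"), (2, "b")):
            idx = np.flatnonzero(counts[:, j] >= copy)
            if idx.size == 0:
                continue
            rows_og.append(og_ids[idx])
            rows_org.append(np.full(idx.size, org))
            rows_gene.append(np.char.add(f"{org}.g", np.char.add(
                np.char.zfill(idx.astype(str), 5), suffix)))
    memberships = pd.DataFrame(
        {
            "og_id": np.concatenate(rows_og),
            "organism": np.concatenate(rows_org),
            "gene_id": np.concatenate(rows_gene),
        }
    )
    orthology = OrthologyTable(memberships)

    # ----- pathways over reference-covered groups ------------------------
    ref_j = 0
    eligible = np.flatnonzero(counts[:, ref_j] >= 1)
    lo, hi = config.pathway_size_range
    if hi > eligible.size:
        raise SimulationError("pathway size exceeds reference-covered group count")
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    pathway_names = [f"PW{j:03d}" for j in range(config.n_pathways)]
    pathway_og_idx: dict[str, np.ndarray] = {}
    pathways: dict[str, frozenset[str]] = {}
    for name, size in zip(pathway_names, sizes):
        chosen = np.sort(rng.choice(eligible, size=int(size), replace=False))
        pathway_og_idx[name] = chosen
        pathways[name] = frozenset(
            f"{orgs[ref_j]}.g{i:05d}a" for i in chosen
        )
    pathway_set = PathwaySet(
        pathways=pathways,
        descriptions={n: "synthetic pathway" for n in pathway_names},
    )

    housekeeping = tuple(pathway_names[: config.n_housekeeping])

    # ----- conserved true expression with planted structure --------------
    # exactly round(q*n) groups expressed per tissue overall (sampling
    # without replacement): the realized expressed fraction equals q, the
    # regime percentile calibration presumes.  House-keeping groups draw
    # their elevated rate first; the balanced remainder fills from the rest.
    base = np.zeros((n_ogs, n_tis), dtype=bool)
    k_expr = round(config.q_expressed * n_ogs)
    hk_ogs = np.array(sorted(
        {int(i) for n in housekeeping for i in pathway_og_idx[n]}
    ), dtype=int)
    if hk_ogs.size:
        base[hk_ogs, :] = rng.random((hk_ogs.size, n_tis)) < config.q_housekeeping
    rest = np.setdiff1d(np.arange(n_ogs), hk_ogs)
    for t in range(n_tis):
        need = max(0, k_expr - int(base[:, t].sum()))
        base[rng.permutation(rest)[:need], t] = True

    # the reference organism *is* the conserved baseline; epsilon perturbs
    # the model organisms relative to it
    eps_flip = rng.random((n_org, n_ogs, n_tis)) < config.epsilon
    eps_flip[0] = False
    true = base[None, :, :] ^ eps_flip

    plan: list[tuple[str, int, tuple[str, ...], float]] = []
    if config.planted_divergences is not None:
        for pw, tissue, label, ff in config.planted_divergences:
            if pw not in pathway_og_idx:
                raise SimulationError(f"planted pathway {pw!r} does not exist")
            if tissue not in tissues:
                raise SimulationError(f"planted tissue {tissue!r} not in panel")
            divergent = tuple(label.split("+"))
            if not set(divergent) <= set(config.models):
                raise SimulationError(f"planted organisms {label!r} not model organisms")
            plan.append((pw, tissues.index(tissue), divergent, float(ff)))
    else:
        classes = config.divergence_classes()
        n_planted = config.n_planted_per_class * len(classes)
        plantable = pathway_names[config.n_housekeeping:]
        candidates = [(p, t) for p in plantable for t in range(n_tis)]
        if n_planted > len(candidates):
            raise SimulationError("not enough pathway–tissue pairs to plant")
        if n_planted > 0:
            pick = rng.choice(len(candidates), size=n_planted, replace=False)
            for k, ci in enumerate(pick):
                pw, t_idx = candidates[int(ci)]
                plan.append((pw, t_idx, classes[k % len(classes)],
                             config.flip_fraction))
    planted_rows = []
    for pw, t_idx, divergent, ff in plan:
        ogs_p = pathway_og_idx[pw]
        n_flip = max(1, round(ff * ogs_p.size))
        flip_ogs = rng.choice(ogs_p, size=n_flip, replace=False)
        for org in divergent:
            true[orgs.index(org), flip_ogs, t_idx] ^= True
        planted_rows.append(
            {
                "pathway": pw,
                "tissue": tissues[t_idx],
                "divergent": "+".join(divergent),
                "expected_group": config.expected_group(divergent),
                "n_flipped_ogs": int(n_flip),
            }
        )
    planted = pd.DataFrame(
        planted_rows,
        columns=["pathway", "tissue", "divergent", "expected_group", "n_flipped_ogs"],
    )

    # ----- scores ---------------------------------------------------------
    expression: dict[str, ExpressionTable] = {}
    for j, org in enumerate(orgs):
        scale = config.score_scale.get(org, 1.0)
        gene_names: list[np.ndarray] = []
        gene_state: list[np.ndarray] = []
        for copy, suffix in ((1, "a"), (2, "b")):
            idx = np.flatnonzero(counts[:, j] >= copy)
            if idx.size == 0:
                continue
            gene_names.append(np.char.add(f"{org}.g", np.char.add(
                np.char.zfill(idx.astype(str), 5), suffix)))
            gene_state.append(true[j, idx, :])
        if config.n_unassigned_genes:
            extra = np.array(
                [f"{org}.u{k:04d}" for k in range(config.n_unassigned_genes)]
            )
            gene_names.append(extra)
            gene_state.append(
                rng.random((config.n_unassigned_genes, n_tis)) < config.q_expressed
            )
        names = np.concatenate(gene_names)
        state = np.concatenate(gene_state, axis=0)
        n_genes = names.size

        has_score = rng.random((n_genes, n_tis)) >= config.p_missing_score
        frames = []
        for channel in config.channels:
            sd = config.score_sd * (1.2 if channel == "integrated" else 1.0)
            loc = np.where(state, config.loc_expressed, config.loc_unexpressed)
            raw = rng.normal(loc, sd) * scale
            if config.tie_rate > 0:
                grid = 0.5 * scale
                tie = rng.random((n_genes, n_tis)) < config.tie_rate
                raw[tie] = np.round(raw[tie] / grid) * grid
            raw = np.round(raw, 6)
            gi, ti = np.nonzero(has_score)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": names[gi],
                        "tissue": np.asarray(tissues, dtype=object)[ti],
                        "score": raw[gi, ti],
                        "channel": channel,
                    }
                )
            )
        records = pd.concat(frames, ignore_index=True)
        meta = {t: int(config.n_datasets.get(org, 2)) for t in tissues}
        expression[org] = ExpressionTable(organism=org, records=records,
                                          tissue_meta=meta)

    # ----- annotations (GO-style terms, interactions) --------------------
    go_tables, ppi_tables = _generate_annotations(config, rng, counts, orgs, og_ids)

    truth = GroundTruth(
        og_counts=pd.DataFrame(counts, index=og_ids, columns=orgs),
        true_expression={
            org: pd.DataFrame(true[j], index=og_ids, columns=tissues)
            for j, org in enumerate(orgs)
        },
        planted=planted,
        housekeeping=housekeeping,
        pathway_ogs={
            n: tuple(_og_id(i) for i in idx) for n, idx in pathway_og_idx.items()
        },
    )
    return SyntheticData(
        config=config,
        orthology=orthology,
        pathways=pathway_set,
        expression=expression,
        go_annotations=go_tables,
        interactions=ppi_tables,
        truth=truth,
    )


def _generate_annotations(config, rng, counts, orgs, og_ids):
    """Conserved term/interaction layers with per-organism dropout."""
    n_ogs = counts.shape[0]
    n_annot = min(config.n_annotated_ogs, n_ogs)
    annot_ogs = rng.choice(n_ogs, size=n_annot, replace=False)
    terms = np.array([f"GO:{k:07d}" for k in range(config.n_go_terms)])
    codes = np.array(["IDA", "IMP", "TAS", "ISS", "IEA"])
    og_terms = {
        int(i): rng.choice(config.n_go_terms, size=int(rng.integers(1, 4)),
                           replace=False)
        for i in annot_ogs
    }
    go_tables: dict[str, AnnotationTable] = {}
    for j, org in enumerate(orgs):
        rows = []
        for i, t_idx in og_terms.items():
            if counts[i, j] < 1 or rng.random() > 0.8:
                continue
            gene = f"{org}.g{i:05d}a"
            for t in t_idx:
                rows.append((gene, terms[t], codes[int(rng.integers(len(codes)))]))
        go_tables[org] = AnnotationTable(
            organism=org, kind="term",
            pairs=pd.DataFrame(rows, columns=["gene_id", "term", "evidence_code"]),
        )
    ppi_tables: dict[str, AnnotationTable] = {}
    n_int = config.n_interactions
    ia = rng.choice(n_ogs, size=n_int)
    ib = rng.choice(n_ogs, size=n_int)
    base_conf = rng.uniform(0.2, 1.0, size=n_int)
    for j, org in enumerate(orgs):
        rows = []
        for k in range(n_int):
            i1, i2 = int(ia[k]), int(ib[k])
            if counts[i1, j] < 1 or counts[i2, j] < 1 or rng.random() > 0.85:
                continue
            conf = float(np.clip(base_conf[k] + rng.normal(0, 0.05), 0, 1))
            rows.append(
                (f"{org}.g{i1:05d}a", f"{org}.g{i2:05d}a", round(conf, 4))
            )
        ppi_tables[org] = AnnotationTable(
            organism=org, kind="interaction",
            pairs=pd.DataFrame(rows, columns=["gene1", "gene2", "confidence"]),
        )
    return go_tables, ppi_tables


def evaluate_recovery(
    assignments: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Recovery rate per planted divergence class.

    A planted (pathway, tissue) pair is recovered when the assignment table
    puts it in its implied group (divergence in organism X implies the
    group of the other two; divergence in a pair implies the remaining
    single organism).  Pairs missing from the assignment table, or left
    unassigned, count as not recovered.  With no planting the result is an
    empty frame.
    """
    if truth.planted.empty:
        return pd.DataFrame(columns=["divergent", "n_planted", "n_recovered",
                                     "recovery"])
    merged = truth.planted.merge(
        assignments[["pathway", "tissue", "group"]],
        on=["pathway", "tissue"],
        how="left",
    )
    merged["recovered"] = merged["group"] == merged["expected_group"]
    out = (
        merged.groupby("divergent", sort=True)
        .agg(n_planted=("recovered", "size"), n_recovered=("recovered", "sum"))
        .reset_index()
    )
    out["recovery"] = out["n_recovered"] / out["n_planted"]
    return out
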