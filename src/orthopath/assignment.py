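"""PCA of Jaccard vectors and organism-group assignment.

Each retained pathway–tissue pair is a point in JI space with one
coordinate per model organism.  A principal component analysis (centering
only, no scaling by default) is run purely as an ordination: PC1 captures
the overall level of agreement with the reference, while PC2 and PC3
separate the model organisms from one another.  Loadings follow the classic
convention ``loading[v, k] = component_k[v] * sqrt(eigenvalue_k)``.

Pairs are ranked by Euclidean distance from the center of the PC2–PC3
plane (scores are mean-centered by construction, so the center is the
origin), and the top-N most extreme pairs are assigned to one of six
organism groups: the angularly nearest of the three loading directions in
that plane — "this model organism agrees with the reference better than the
others" — or of their antipodes, where the direction opposite organism X is
the shared group of the other two model organisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PCAResult",
    "run_pca",
    "rank_by_center_distance",
    "assign_groups",
    "group_summary",
    "pair_group_label",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


class AssignmentError(ValueError):
    pass


class ZeroVarianceError(AssignmentError):
    """All retained JI vectors identical: ordination is undefined."""


@dataclass(frozen=True)
class PCAResult:
    variables: tuple[str, ...]           # model organisms, column order of the input
    scores: pd.DataFrame                 # index (pathway, tissue); columns PC1..PCk
    components: np.ndarray               # k x n_vars, orthonormal rows
    explained_variance: np.ndarray       # eigenvalues, descending
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # n_vars x k

    @property
    def n_components(self) -> int:
        return len(self.explained_variance)

    def loading_angle(self, variable: str, x_pc: int = 2, y_pc: int = 3) -> float:
        """Angle (radians) of one variable's loading in the x_pc–y_pc plane."""
        lx = self.loadings.loc[variable, f"PC{x_pc}"]
        ly = self.loadings.loc[variable, f"PC{y_pc}"]
        if math.hypot(lx, ly) < 1e-12:
            raise AssignmentError(
                f"loading of {variable!r} has zero projection on PC{x_pc}/PC{y_pc}"
            )
        return math.atan2(ly, lx)


def run_pca(
    ji_records: pd.DataFrame,
    models: Sequence[str],
    min_expressed: int = 5,
    scale: bool = False,
    expressed_scope: str = "union",
) -> PCAResult:
    """PCA over pathway–tissue JI vectors.

    Pairs are retained only when every model-organism JI is defined and at
    least ``min_expressed`` pathway members are expressed in the tissue
    (by default counting the union over all organisms; ``expressed_scope=
    "reference"`` gates on the reference organism's expressed set instead).

    Component signs are fixed deterministically: the largest-magnitude
    entry of each component is made positive.
    """
    models = tuple(models)
    ji_cols = [f"ji_{m}" for m in models]
    gate_col = "n_expressed_union" if expressed_scope == "union" else "n_expressed_ref"
    mask = ji_records[ji_cols].notna().all(axis=1) & (
        ji_records[gate_col] >= min_expressed
    )
    kept = ji_records.loc[mask].sort_values(["pathway", "tissue"], kind="mergesort")
    if len(kept) < len(models):
        raise AssignmentError(
            f"only {len(kept)} usable pathway–tissue pairs for {len(models)} variables"
        )
    X = kept[ji_cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise AssignmentError("non-finite JI values")
    var = X.var(axis=0, ddof=1)
    if var.sum() <= 0:
        raise ZeroVarianceError("all retained JI vectors are identical")
    if scale:
        sd = np.sqrt(var)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    k = len(models)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    ev = pca.explained_variance_.copy()
    ratio = pca.explained_variance_ratio_.copy()
    pc_names = [f"PC{i + 1}" for i in range(k)]
    score_df = pd.DataFrame(
        scores,
        columns=pc_names,
        index=pd.MultiIndex.from_frame(kept[["pathway", "tissue"]]),
    )
    loadings = pd.DataFrame(
        components.T * np.sqrt(ev)[np.newaxis, :], index=list(models), columns=pc_names
    )
    return PCAResult(
        variables=models,
        scores=score_df,
        components=components,
        explained_variance=ev,
        explained_variance_ratio=ratio,
        loadings=loadings,
    )


def rank_by_center_distance(pca: PCAResult) -> pd.DataFrame:
    """Order pairs by distance from the PC2–PC3 center, most extreme first.

    Ties are broken lexicographically by (pathway, tissue) so the ranking
    is deterministic.  Rank is 1-based.
    """
    if pca.n_components < 3:
        raise AssignmentError("PC2 and PC3 require at least 3 components")
    df = pca.scores.reset_index()
    df["center_distance"] = np.hypot(df["PC2"], df["PC3"])
    df = df.sort_values(
        ["center_distance", "pathway", "tissue"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def pair_group_label(excluded: str, models: Sequence[str]) -> str:
    """Label of the shared group opposite organism ``excluded``."""
    others = [m for m in models if m != excluded]
    return " & ".join(others)


def _wrapped_angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % (2 * math.pi)
    return min(d, 2 * math.pi - d)


def reference_directions(pca: PCAResult) -> dict[str, float]:
    """The six reference angles in the PC2–PC3 plane.

    Three loading directions labelled by their model organism, plus their
    antipodes labelled by the complementary organism pair.
    """
    models = pca.variables
    dirs: dict[str, float] = {}
    for m in models:
        ang = pca.loading_angle(m)
        dirs[m] = ang
        anti = math.atan2(-math.sin(ang), -math.cos(ang))
        dirs[pair_group_label(m, models)] = anti
    return dirs


def assign_groups(
    ranked: pd.DataFrame, pca: PCAResult, top_n: int = 200
) -> pd.DataFrame:
    """Assign each of the ``top_n`` most extreme pairs to its nearest group.

    The group of a pair is the reference direction (loading or antipode)
    with the smallest angular distance to the pair's (PC2, PC3) vector;
    pairs below the cut stay unassigned.  Equidistant directions (measure-
    zero in practice) resolve to the alphabetically first label.
    """
    dirs = reference_directions(pca)
    labels = sorted(dirs)
    out = ranked.copy()
    groups = []
    for _, row in out.iterrows():
        if row["rank"] > top_n:
            groups.append(UNASSIGNED)
            continue
        ang = math.atan2(row["PC3"], row["PC2"])
        best = min(labels, key=lambda lab: (_wrapped_angle_diff(ang, dirs[lab]), lab))
        groups.append(best)
    out["group"] = groups
    return out


def group_summary(
    assignments: pd.DataFrame,
    ji_records: pd.DataFrame,
    models: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Counts and mean JI per organism group over the assigned pairs.

    Returns frames: ``groups`` (pairs, distinct pathways, mean JI of the
    group's own organisms), ``per_tissue`` (pathways per group per tissue)
    and ``single_organism_pathways`` (the distinct pathways over the three
    single-organism groups combined).
    """
    assigned = assignments[assignments["group"] != UNASSIGNED]
    merged = assigned.merge(ji_records, on=["pathway", "tissue"], how="left")
    rows = []
    for group, sub in merged.groupby("group", sort=True):
        own = [m for m in models if m in group.split(" & ")]
        ji_vals = sub[[f"ji_{m}" for m in own]].to_numpy().ravel()
        rows.append(
            {
                "group": group,
                "n_pairs": len(sub),
                "n_pathways": sub["pathway"].nunique(),
                "mean_ji": float(np.nanmean(ji_vals)) if len(ji_vals) else np.nan,
            }
        )
    groups = pd.DataFrame(rows)
    per_tissue = (
        merged.groupby(["group", "tissue"], sort=True)["pathway"]
        .nunique()
        .rename("n_pathways")
        .reset_index()
    )
    single = merged[merged["group"].isin(models)]
    single_paths = pd.DataFrame(
        {"pathway": sorted(single["pathway"].unique())}
    )
    return {
        "groups": groups,
        "per_tissue": per_tissue,
        "single_organism_pathways": single_paths,
    }
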