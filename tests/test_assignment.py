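"""PCA ordination, center-distance ranking and organism-group geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from orthopath import assign_groups, group_summary, rank_by_center_distance, run_pca
from orthopath.assignment import (
    AssignmentError,
    PCAResult,
    ZeroVarianceError,
    pair_group_label,
    reference_directions,
)

MODELS = ("mouse", "rat", "pig")


def ji_frame(X, n_expressed=10):
    n = len(X)
    return pd.DataFrame(
        {
            "pathway": [f"P{i:03d}" for i in range(n)],
            "tissue": ["liver"] * n,
            "ji_mouse": X[:, 0],
            "ji_rat": X[:, 1],
            "ji_pig": X[:, 2],
            "n_expressed_union": n_expressed,
            "n_expressed_ref": n_expressed,
        }
    )


def eigh_oracle(X):
    """Independent route: eigendecomposition of the sample covariance."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class TestRunPca:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 3)) * np.array([2.0, 1.0, 0.5])
        pca = run_pca(ji_frame(X), MODELS, min_expressed=5)
        w, v = eigh_oracle(X)
        assert np.allclose(pca.explained_variance, w, atol=1e-8)
        assert np.allclose(pca.explained_variance_ratio, w / w.sum(), atol=1e-8)
        for k in range(3):
            # components equal up to sign; our sign rule then fixes scores too
            assert np.allclose(np.abs(pca.components[k]), np.abs(v[:, k]), atol=1e-8)
        Xc = X - X.mean(axis=0)
        assert np.allclose(pca.scores.to_numpy(), Xc @ pca.components.T, atol=1e-8)

    def test_known_independent_variances(self):
        # exactly orthogonal mean-zero columns with sample variances 4, 1, 0.25
        H = hadamard(8).astype(float)
        var = np.array([4.0, 1.0, 0.25])
        X = H[:, 1:4] * np.sqrt(var * 7 / 8)
        pca = run_pca(ji_frame(X), MODELS, min_expressed=5)
        assert np.allclose(pca.explained_variance_ratio, var / var.sum(), atol=1e-12)
        assert np.allclose(np.abs(pca.components), np.eye(3), atol=1e-9)

    def test_loading_definition_holds_identically(self):
        rng = np.random.default_rng(7)
        pca = run_pca(ji_frame(rng.normal(size=(30, 3))), MODELS, 5)
        for k in range(3):
            expect = pca.components[k] * math.sqrt(pca.explained_variance[k])
            assert np.allclose(pca.loadings[f"PC{k + 1}"].to_numpy(), expect)

    def test_ratio_sum_is_one(self):
        rng = np.random.default_rng(8)
        pca = run_pca(ji_frame(rng.normal(size=(40, 3))), MODELS, 5)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_rows_raise_zero_variance(self):
        X = np.ones((10, 3)) * 0.4
        with pytest.raises(ZeroVarianceError):
            run_pca(ji_frame(X), MODELS, 5)

    def test_too_few_rows_rejected(self):
        with pytest.raises(AssignmentError, match="usable"):
            run_pca(ji_frame(np.zeros((2, 3))), MODELS, 5)

    def test_min_expressed_gate_filters_pairs(self):
        rng = np.random.default_rng(9)
        df = ji_frame(rng.normal(size=(30, 3)))
        df.loc[:9, "n_expressed_union"] = 3
        pca = run_pca(df, MODELS, min_expressed=5)
        assert len(pca.scores) == 20

    def test_undefined_ji_rows_dropped(self):
        rng = np.random.default_rng(10)
        df = ji_frame(rng.normal(size=(30, 3)))
        df.loc[:4, "ji_rat"] = np.nan
        assert len(run_pca(df, MODELS, 5).scores) == 25


class TestRanking:
    def make_pca(self, pc23, pc1=None):
        n = len(pc23)
        scores = pd.DataFrame(
            {
                "PC1": pc1 if pc1 is not None else np.zeros(n),
                "PC2": [x for x, _ in pc23],
                "PC3": [y for _, y in pc23],
            },
            index=pd.MultiIndex.from_tuples(
                [(f"P{i:03d}", "liver") for i in range(n)],
                names=["pathway", "tissue"],
            ),
        )
        loadings = pd.DataFrame(
            {
                "PC1": [0.5, 0.5, 0.5],
                "PC2": [-0.3, 0.6, -0.3],
                "PC3": [0.5, 0.0, -0.5],
            },
            index=list(MODELS),
        )
        return PCAResult(
            variables=MODELS,
            scores=scores,
            components=np.eye(3),
            explained_variance=np.array([3.0, 2.0, 1.0]),
            explained_variance_ratio=np.array([0.5, 1 / 3, 1 / 6]),
            loadings=loadings,
        )

    def test_three_four_five_distance(self):
        ranked = rank_by_center_distance(self.make_pca([(3.0, 4.0), (0.0, 0.0)]))
        assert ranked.iloc[0]["center_distance"] == pytest.approx(5.0)

    def test_center_point_ranked_last(self):
        ranked = rank_by_center_distance(
            self.make_pca([(0.0, 0.0), (1.0, 0.0), (0.5, 0.5)])
        )
        assert ranked.iloc[-1]["pathway"] == "P000"
        assert ranked.iloc[-1]["rank"] == 3

    def test_order_matches_sort_oracle(self):
        rng = np.random.default_rng(12)
        pts = [tuple(p) for p in rng.normal(size=(10, 2))]
        ranked = rank_by_center_distance(self.make_pca(pts))
        oracle = sorted(range(10), key=lambda i: -math.hypot(*pts[i]))
        assert list(ranked["pathway"]) == [f"P{i:03d}" for i in oracle]

    def test_ties_break_lexicographically(self):
        ranked = rank_by_center_distance(self.make_pca([(1.0, 0.0), (0.0, 1.0)]))
        assert list(ranked["pathway"]) == ["P000", "P001"]


class TestGroupGeometry:
    def make_pca_with_loadings(self, loadings_23, pc23):
        n = len(pc23)
        scores = pd.DataFrame(
            {
                "PC1": np.zeros(n),
                "PC2": [x for x, _ in pc23],
                "PC3": [y for _, y in pc23],
            },
            index=pd.MultiIndex.from_tuples(
                [(f"P{i:03d}", "liver") for i in range(n)],
                names=["pathway", "tissue"],
            ),
        )
        loadings = pd.DataFrame(
            {
                "PC1": [0.5] * 3,
                "PC2": [loadings_23[m][0] for m in MODELS],
                "PC3": [loadings_23[m][1] for m in MODELS],
            },
            index=list(MODELS),
        )
        return PCAResult(
            variables=MODELS, scores=scores, components=np.eye(3),
            explained_variance=np.array([3.0, 2.0, 1.0]),
            explained_variance_ratio=np.array([0.5, 1 / 3, 1 / 6]),
            loadings=loadings,
        )

    DEFAULT_LOADINGS = {
        "mouse": (math.cos(math.radians(100)), math.sin(math.radians(100))),
        "rat": (math.cos(math.radians(-20)), math.sin(math.radians(-20))),
        "pig": (math.cos(math.radians(-135)), math.sin(math.radians(-135))),
    }

    def test_point_on_loading_gets_that_organism(self):
        pca = self.make_pca_with_loadings(
            self.DEFAULT_LOADINGS, [self.DEFAULT_LOADINGS["pig"]]
        )
        out = assign_groups(rank_by_center_distance(pca), pca, top_n=1)
        assert out.iloc[0]["group"] == "pig"

    def test_antipode_of_pig_is_mouse_and_rat(self):
        px, py = self.DEFAULT_LOADINGS["pig"]
        pca = self.make_pca_with_loadings(self.DEFAULT_LOADINGS, [(-px, -py)])
        out = assign_groups(rank_by_center_distance(pca), pca, top_n=1)
        assert out.iloc[0]["group"] == "mouse & rat"

    def test_pair_labels_follow_model_order(self):
        assert pair_group_label("pig", MODELS) == "mouse & rat"
        assert pair_group_label("rat", MODELS) == "mouse & pig"
        assert pair_group_label("mouse", MODELS) == "rat & pig"

    @pytest.mark.parametrize("seed", range(3))
    def test_unit_circle_matches_nearest_angle_oracle(self, seed):
        """360 points at 1 degree spacing: boundaries at angular bisectors."""
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * math.pi, size=3))
        if np.min(np.diff(angles)) < 0.2:  # keep loadings non-degenerate
            angles = np.array([0.3, 2.1, 4.4])
        loadings = {
            m: (math.cos(a), math.sin(a)) for m, a in zip(MODELS, angles)
        }
        pts = [
            (math.cos(math.radians(d)), math.sin(math.radians(d)))
            for d in range(360)
        ]
        pca = self.make_pca_with_loadings(loadings, pts)
        out = assign_groups(rank_by_center_distance(pca), pca, top_n=360)
        refs = {}
        for m, a in zip(MODELS, angles):
            refs[m] = a
            refs[pair_group_label(m, MODELS)] = (a + math.pi) % (2 * math.pi)

        def brute(d):
            th = math.radians(d)
            def dist(a):
                x = abs(th - a) % (2 * math.pi)
                return min(x, 2 * math.pi - x)
            best = min(sorted(refs), key=lambda lab: (dist(refs[lab]), lab))
            return best

        got = out.set_index("pathway")["group"]
        for i, d in enumerate(range(360)):
            assert got[f"P{i:03d}"] == brute(d)

    def test_rotation_equivariance(self):
        """Rotating scores and loadings together leaves groups unchanged."""
        rng = np.random.default_rng(5)
        pts = [tuple(p) for p in rng.normal(size=(40, 2))]
        base = self.make_pca_with_loadings(self.DEFAULT_LOADINGS, pts)
        out_base = assign_groups(rank_by_center_distance(base), base, top_n=40)
        theta = 1.1
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        rot_pts = [tuple(R @ np.array(p)) for p in pts]
        rot_loadings = {
            m: tuple(R @ np.array(v)) for m, v in self.DEFAULT_LOADINGS.items()
        }
        rot = self.make_pca_with_loadings(rot_loadings, rot_pts)
        out_rot = assign_groups(rank_by_center_distance(rot), rot, top_n=40)
        merged = out_base.merge(out_rot, on="pathway", suffixes=("_a", "_b"))
        assert (merged["group_a"] == merged["group_b"]).all()

    def test_degenerate_loading_rejected(self):
        loadings = dict(self.DEFAULT_LOADINGS, rat=(0.0, 0.0))
        pca = self.make_pca_with_loadings(loadings, [(1.0, 0.0)])
        with pytest.raises(AssignmentError, match="zero projection"):
            assign_groups(rank_by_center_distance(pca), pca, top_n=1)

    def test_reference_directions_has_six_labels(self):
        pca = self.make_pca_with_loadings(self.DEFAULT_LOADINGS, [(1.0, 0.0)])
        dirs = reference_directions(pca)
        assert set(dirs) == {"mouse", "rat", "pig", "mouse & rat",
                             "mouse & pig", "rat & pig"}


class TestGroupSummary:
    def test_counts_partition_top_n(self, small_run):
        groups = small_run.summaries["groups"]
        top_n = small_run.config.top_n
        assigned = (small_run.assignments["group"] != "unassigned").sum()
        assert groups["n_pairs"].sum() == assigned == min(
            top_n, len(small_run.assignments)
        )

    def test_one_pair_per_group(self):
        geometry = TestGroupGeometry()
        pts = []
        for m, (x, y) in geometry.DEFAULT_LOADINGS.items():
            pts.append((x, y))
            pts.append((-x, -y))
        pca = geometry.make_pca_with_loadings(geometry.DEFAULT_LOADINGS, pts)
        out = assign_groups(rank_by_center_distance(pca), pca, top_n=6)
        ji = pd.DataFrame(
            {
                "pathway": [f"P{i:03d}" for i in range(6)],
                "tissue": ["liver"] * 6,
                "ji_mouse": 0.5, "ji_rat": 0.5, "ji_pig": 0.5,
            }
        )
        summary = group_summary(out, ji, MODELS)
        assert (summary["groups"]["n_pairs"] == 1).all()
        assert len(summary["groups"]) == 6
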