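"""Pathway expression fractions, the 85% rule and breadth summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from orthopath import profile_pathways, summarize_expression_breadth
from orthopath.activity import ActivityError
from orthopath.expression import ExpressionCalls


def calls_from(org, entries):
    """entries: {(og, tissue): expressed_bool or None-for-no-info}."""
    rows = [
        {"entity": og, "tissue": t, "score": 1.0 + bool(v), "expressed": bool(v)}
        for (og, t), v in entries.items()
        if v is not None
    ]
    return ExpressionCalls(organism=org, calls=pd.DataFrame(
        rows, columns=["entity", "tissue", "score", "expressed"]))


def grid_calls(org, n_ogs, tissues, expressed_fn, info_fn=lambda og, t: True):
    entries = {}
    for i, t in itertools.product(range(n_ogs), tissues):
        og = f"og{i}"
        entries[(og, t)] = expressed_fn(i, t) if info_fn(i, t) else None
    return calls_from(org, entries)


class TestProfilePathways:
    def test_boundary_fraction_is_inclusive(self):
        tissues = ["liver"]
        for n_expr, expect in ((17, True), (16, False)):
            calls = grid_calls("h", 20, tissues, lambda i, t: i < n_expr)
            profiles, _ = profile_pathways(
                {"P": frozenset(f"og{i}" for i in range(20))},
                {"h": calls}, tissues, min_info=5, expressed_fraction=0.85,
            )
            row = profiles.iloc[0]
            assert row["n_info"] == 20 and row["n_expressed"] == n_expr
            assert bool(row["expressed"]) is expect

    def test_uninformative_ogs_excluded_from_denominator(self):
        tissues = ["liver"]
        calls = grid_calls("h", 10, tissues, lambda i, t: i < 4,
                           info_fn=lambda i, t: i < 5)
        profiles, _ = profile_pathways(
            {"P": frozenset(f"og{i}" for i in range(10))},
            {"h": calls}, tissues, min_info=5, expressed_fraction=0.85,
        )
        row = profiles.iloc[0]
        assert row["n_info"] == 5 and row["fraction"] == pytest.approx(0.8)

    def test_hand_computed_toy_fractions(self):
        """3 pathways x 2 tissues x 2 organisms against direct counting."""
        rng = np.random.default_rng(3)
        tissues = ["liver", "heart"]
        ogs = [f"og{i}" for i in range(12)]
        pathway_ogs = {
            "P0": frozenset(ogs[0:6]), "P1": frozenset(ogs[3:9]),
            "P2": frozenset(ogs[6:12]),
        }
        state = {
            org: {(og, t): rng.random() < 0.6 for og in ogs for t in tissues}
            for org in ("h", "m")
        }
        og_calls = {org: calls_from(org, state[org]) for org in ("h", "m")}
        profiles, _ = profile_pathways(pathway_ogs, og_calls, tissues,
                                       min_info=1, expressed_fraction=0.85)
        assert len(profiles) == 12
        for _, row in profiles.iterrows():
            members = pathway_ogs[row["pathway"]]
            expect = sum(state[row["organism"]][(og, row["tissue"])] for og in members)
            assert row["n_expressed"] == expect
            assert row["fraction"] == pytest.approx(expect / len(members))

    def test_low_information_pathways_excluded(self):
        tissues = ["liver"]
        calls = grid_calls("h", 4, tissues, lambda i, t: True)
        profiles, excluded = profile_pathways(
            {"small": frozenset(f"og{i}" for i in range(4))},
            {"h": calls}, tissues, min_info=5, expressed_fraction=0.85,
        )
        assert excluded == ["small"] and profiles.empty

    def test_empty_tissue_list_rejected(self):
        with pytest.raises(ActivityError, match="empty tissue list"):
            profile_pathways({}, {}, [], 5, 0.85)

    def test_lower_threshold_never_reduces_expressed_counts(self, small_run):
        """Monotonicity that links the pathway rule to the gene cutoff."""
        base = small_run
        loose, _ = profile_pathways(
            base.pathway_ogs, base.og_calls, base.tissues,
            min_info=5, expressed_fraction=0.70,
        )
        strict = base.profiles
        merged = strict.merge(loose, on=["pathway", "tissue", "organism"],
                              suffixes=("_strict", "_loose"))
        assert (merged["expressed_loose"] >= merged["expressed_strict"]).all()


class TestBreadth:
    def make_profiles(self, spec):
        """spec: {(pathway, organism): set of expressed tissues}."""
        tissues = [f"t{i}" for i in range(7)]
        rows = []
        for (p, org), expr in spec.items():
            for t in tissues:
                rows.append({"pathway": p, "tissue": t, "organism": org,
                             "n_info": 10, "n_expressed": 9 if t in expr else 1,
                             "fraction": 0.9 if t in expr else 0.1,
                             "expressed": t in expr})
        return pd.DataFrame(rows)

    def test_broad_and_specific_classification(self):
        allt = {f"t{i}" for i in range(7)}
        profiles = self.make_profiles({
            ("hk", "h"): allt, ("hk", "m"): allt,
            ("ns", "h"): {"t0"}, ("ns", "m"): {"t0"},
        })
        breadth, counts = summarize_expression_breadth(profiles, broad_tissue_count=3)
        b = breadth.set_index(["pathway", "organism"])
        assert (b.loc[("hk", "h"), "n_tissues_expressed"] == 7
                and bool(b.loc[("hk", "h"), "broadly_expressed"]))
        assert (b.loc[("ns", "m"), "n_tissues_expressed"] == 1
                and not bool(b.loc[("ns", "m"), "broadly_expressed"]))

    def test_broad_requires_every_organism(self):
        allt = {f"t{i}" for i in range(7)}
        profiles = self.make_profiles({("p", "h"): allt, ("p", "m"): {"t0"}})
        breadth, _ = summarize_expression_breadth(profiles, 3)
        assert not breadth["broadly_expressed"].any()

    def test_tissue_counts_consistent_with_profiles(self, small_run):
        profiles = small_run.profiles
        counts = small_run.tissue_counts.set_index(["tissue", "organism"])
        direct = profiles.groupby(["tissue", "organism"])["expressed"].sum()
        assert (counts["n_pathways_expressed"] == direct).all()


def test_housekeeping_pathways_are_the_broad_ones():
    """Planted house-keeping pathways, and only those, reach breadth >= 3 in
    every organism.  Needs a few dozen informative OGs per pathway so the
    ~0.9 per-OG expressed probability clears the 0.85 rule reliably."""
    from orthopath import Config, SimulationConfig, generate, run_all

    cfg = SimulationConfig(rng_seed=13, n_ogs=1500, n_pathways=16,
                           pathway_size_range=(40, 80), n_housekeeping=4,
                           n_planted_per_class=1)
    data = generate(cfg)
    res = run_all(Config(rng_seed=13, top_n=40), data)
    breadth = res.breadth
    broad = set(breadth.loc[breadth["broadly_expressed"], "pathway"])
    hk = set(data.truth.housekeeping) & set(breadth["pathway"])
    assert broad == hk
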