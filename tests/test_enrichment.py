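"""Hypergeometric tails, BH adjustment, tiers, and term networks."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxarray.enrichment import (
    EnrichmentAnalysis,
    bh_adjust,
    build_term_network,
    hypergeom_enrich,
    tier_and_filter,
)
from toxarray.exceptions import ValidationError
from toxarray.io import GeneSetCollection
from toxarray.simulate import simulate_geneset_collection


def exact_tail(N, K, n, k):
    """P[X >= k] by exact-fraction tail summation."""
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


class TestHypergeom:
    def test_saturated_overlap_exact_probability(self):
        genes = [f"G{i}" for i in range(20)]
        coll = GeneSetCollection({"T": ("t", set(genes[:5]))})
        rec = hypergeom_enrich(set(genes[:5]), coll, genes)
        assert rec.loc[0, "p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)
        assert rec.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-12)

    def test_query_equals_background_saturates(self):
        genes = [f"G{i}" for i in range(30)]
        coll = GeneSetCollection({
            "T1": ("a", set(genes[:7])), "T2": ("b", set(genes[10:25])),
        })
        rec = hypergeom_enrich(genes, coll, genes)
        assert (rec["fold_enrichment"] == 1.0).all()
        assert (rec["p"] == 1.0).all()

    def test_expected_overlap_is_not_significant(self):
        # k exactly at expectation: upper tail must exceed 0.5 in small
        # symmetric cases
        genes = [f"G{i}" for i in range(20)]
        coll = GeneSetCollection({"T": ("t", set(genes[:10]))})
        query = set(genes[:5]) | set(genes[10:15])  # k=5 = n*K/N
        rec = hypergeom_enrich(query, coll, genes)
        assert rec.loc[0, "p"] > 0.5

    def test_terms_intersected_with_background(self):
        coll = GeneSetCollection({"T": ("t", {"A", "B", "Z"})})
        rec = hypergeom_enrich({"A"}, coll, {"A", "B", "C", "D"})
        assert rec.loc[0, "K"] == 2  # Z is outside the background

    def test_query_outside_background_rejected(self):
        coll = GeneSetCollection({"T": ("t", {"A"})})
        with pytest.raises(ValidationError, match="X"):
            hypergeom_enrich({"A", "X"}, coll, {"A", "B"})

    def test_matches_exact_enumeration_on_small_universes(self, rng):
        for _ in range(40):
            N = int(rng.integers(5, 26))
            genes = [f"G{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(genes, K, replace=False))
            query = set(rng.choice(genes, n, replace=False))
            if not query & term:
                continue
            coll = GeneSetCollection({"T": ("t", term)})
            rec = hypergeom_enrich(query, coll, genes)
            k = len(query & term)
            assert rec.loc[0, "p"] == pytest.approx(
                exact_tail(N, K, n, k), rel=1e-10
            )


def naive_bh(pvals):
    """Textbook step-up: p_(i) * m / i with running minimum from the top."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_sorted_input_gives_monotone_output(self, rng):
        p = np.sort(rng.uniform(size=50))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_matches_naive_and_dominates_input(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, naive_bh(np.asarray(pvals)), rtol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])


class TestTiers:
    def _frame(self, fdr, fe=10.0):
        return pd.DataFrame({
            "term_id": [f"T{i}" for i in range(len(fdr))],
            "term_name": "t", "k": 5, "n": 50, "K": 20, "N": 5000,
            "fold_enrichment": fe, "p": fdr, "fdr": fdr,
        })

    @pytest.mark.parametrize(
        "fdr, tier",
        [(0.0094, "significant"), (0.05, "significant"),
         (0.067, "suggestive"), (0.10, "suggestive"), (0.12, "none")],
    )
    def test_tier_boundaries(self, fdr, tier):
        out = tier_and_filter(self._frame([fdr]))
        assert out.loc[0, "tier"] == tier

    def test_low_fold_enrichment_demoted_but_retained(self):
        out = tier_and_filter(self._frame([0.01], fe=2.0))
        assert len(out) == 1
        assert out.loc[0, "tier"] == "none"
        assert not out.loc[0, "fe_pass"]
        out2 = tier_and_filter(self._frame([0.01], fe=2.0), apply_fe=False)
        assert out2.loc[0, "tier"] == "significant"


class TestTermNetwork:
    def _records(self, coll, query):
        recs = []
        for tid, (name, members) in coll.items():
            k = len(members & set(query))
            recs.append({"term_id": tid, "term_name": name, "k": k,
                         "fdr": 0.01})
        return pd.DataFrame(recs)

    def test_identical_terms_fully_similar(self):
        coll = GeneSetCollection({
            "T1": ("a", {"A", "B"}), "T2": ("b", {"A", "B"}),
        })
        g = build_term_network(self._records(coll, ["A", "B"]), coll, ["A", "B"])
        assert g["T1"]["T2"]["similarity"] == pytest.approx(1.0)
        assert g["T1"]["T2"]["weight"] == 2

    def test_disjoint_terms_unconnected(self):
        coll = GeneSetCollection({
            "T1": ("a", {"A"}), "T2": ("b", {"B"}),
        })
        g = build_term_network(self._records(coll, ["A", "B"]), coll, ["A", "B"])
        assert g.number_of_edges() == 0

    def test_edges_match_all_pairs_jaccard_scan(self, rng):
        genes = [f"G{i}" for i in range(40)]
        query = genes[:25]
        coll = GeneSetCollection()
        for t in range(12):
            coll.add(f"T{t}", "t",
                     rng.choice(genes, rng.integers(3, 15), replace=False))
        g = build_term_network(self._records(coll, query), coll, query,
                               min_similarity=0.2)
        for t1, t2 in itertools.combinations(list(coll), 2):
            s1 = coll.members(t1) & set(query)
            s2 = coll.members(t2) & set(query)
            union = s1 | s2
            jac = len(s1 & s2) / len(union) if union else 0.0
            assert g.has_edge(t1, t2) == (jac >= 0.2), (t1, t2)

    def test_node_attributes(self):
        coll = GeneSetCollection({"T1": ("term one", {"A", "B", "C"})})
        g = build_term_network(
            pd.DataFrame([{"term_id": "T1", "term_name": "term one",
                           "k": 2, "fdr": 0.001}]),
            coll, ["A", "B"],
        )
        assert g.nodes["T1"]["k"] == 2
        assert g.nodes["T1"]["neglog10_fdr"] == pytest.approx(3.0)


class TestPlantedRecovery:
    def test_planted_term_ranks_first_in_most_runs(self):
        genes = [f"G{i}" for i in range(800)]
        query = genes[:60]
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            coll, pid = simulate_geneset_collection(
                genes, query, n_terms=40, planted_term_size=40,
                planted_overlap=15, seed=seed,
            )
            res = EnrichmentAnalysis(query, coll, genes, apply_fe=False).fit()
            wins += res.records.iloc[0]["term_id"] == pid
        assert wins >= 0.95 * n_runs

    def test_planted_p_matches_exact_tail(self):
        genes = [f"G{i}" for i in range(24)]
        query = genes[:8]
        coll, pid = simulate_geneset_collection(
            genes, query, n_terms=3, planted_term_size=6,
            planted_overlap=4, term_size_range=(3, 6), seed=7,
        )
        res = EnrichmentAnalysis(query, coll, genes, apply_fe=False).fit()
        row = res.records.set_index("term_id").loc[pid]
        assert row["p"] == pytest.approx(
            exact_tail(24, 6, 8, 4), rel=1e-10
        )
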