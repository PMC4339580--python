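"""EASE scores, kappa agreement, term clustering and cluster scores."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from factorial_de.enrichment import (
    GeneSetCollection,
    cluster_score,
    cluster_terms,
    ease_p,
    enrich_terms,
    kappa,
)
from factorial_de.fixtures import load_fixture


def hypergeom_tail(k_min, n, K, N):
    """Exhaustive enumeration of P(X >= k_min) via binomial coefficients."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) / denom
        for k in range(max(k_min, 0), min(n, K) + 1)
    )


class TestEaseP:
    def test_single_hit_scores_one(self):
        assert ease_p(1, 10, 50, 1000) == 1.0
        assert ease_p(0, 10, 50, 1000) == 1.0

    def test_small_exact_value(self):
        # P(X >= 3) for Hypergeom(N=10, K=5, n=4) = 55/210
        assert ease_p(4, 4, 5, 10) == pytest.approx(55 / 210)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            ease_p(6, 4, 5, 10)
        with pytest.raises(ValueError):
            ease_p(2, 20, 5, 10)

    def test_matches_enumeration_small_grid(self):
        """Spot grid here; the full N <= 60 sweep runs in the acceptance suite."""
        for N in (5, 10, 17, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = 1.0 if k <= 1 else hypergeom_tail(k - 1, n, K, N)
                        assert ease_p(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    @given(
        N=st.integers(2, 80),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_ease_penalization_dominates_fisher(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        fisher = float(hypergeom.sf(k - 1, N, K, n))  # plain P(X >= k)
        assert ease_p(k, n, K, N) >= fisher - 1e-12


class TestEnrichTerms:
    def test_full_membership_ranks_first(self):
        coll = GeneSetCollection.from_sets(
            {
                "tA": ("hit set", {"g1", "g2", "g3", "g4"}),
                "tB": ("decoy", {"g5", "g6", "g7", "g8"}),
            },
            background=[f"g{i}" for i in range(1, 21)],
        )
        res = enrich_terms({"g1", "g2", "g3", "g4"}, coll)
        assert res.index[0] == "tA"
        assert res.loc["tA", "k"] == 4

    def test_disjoint_list_is_empty(self, toy_collection):
        members = frozenset().union(*(m for _, m in toy_collection.terms.values()))
        outside = sorted(toy_collection.background - members)[:5] or None
        if outside:
            res = enrich_terms(outside, toy_collection)
            assert res.empty

    def test_empty_list_rejected(self, toy_collection):
        with pytest.raises(ValueError):
            enrich_terms([], toy_collection)

    def test_every_ease_matches_enumeration(self, toy_collection):
        rng = np.random.default_rng(5)
        gene_list = rng.choice(sorted(toy_collection.background), 20, replace=False)
        res = enrich_terms(gene_list, toy_collection)
        assert not res.empty
        for tid, row in res.iterrows():
            expected = (
                1.0
                if row["k"] <= 1
                else hypergeom_tail(int(row["k"]) - 1, int(row["n"]), int(row["K"]), int(row["N"]))
            )
            assert row["ease_p"] == pytest.approx(expected, abs=1e-12)


class TestKappa:
    def test_identical_sets(self):
        assert kappa({"a", "b"}, {"a", "b"}, 100) == 1.0

    def test_perfect_disagreement(self):
        assert kappa(set(range(10)), set(range(10, 20)), 20) == pytest.approx(-1.0)

    def test_empty_vs_empty(self):
        assert kappa(set(), set(), 100) == 1.0

    def test_background_too_small_rejected(self):
        with pytest.raises(ValueError):
            kappa({1, 2}, {3, 4}, 3)

    @given(
        a=st.sets(st.integers(0, 19)),
        b=st.sets(st.integers(0, 19)),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_formula(self, a, b):
        N = 25
        n11 = len(a & b)
        n10 = len(a - b)
        n01 = len(b - a)
        n00 = N - len(a | b)
        po = (n11 + n00) / N
        pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / N**2
        expected = 1.0 if pe == 1.0 else (po - pe) / (1 - pe)
        assert kappa(a, b, N) == pytest.approx(expected)


class TestClusterScore:
    def test_single_value(self):
        assert cluster_score([0.001]) == pytest.approx(3.0)

    def test_mean_of_exponents(self):
        assert cluster_score([1e-2, 1e-4]) == pytest.approx(3.0)

    def test_equals_neg_log10_geometric_mean(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-12, 1.0, size=20)
        geo = float(np.exp(np.mean(np.log(p))))
        assert cluster_score(p) == pytest.approx(-math.log10(geo), abs=1e-9)

    def test_permutation_invariant(self):
        p = [1e-3, 1e-7, 0.5, 1e-2]
        assert cluster_score(p) == pytest.approx(cluster_score(p[::-1]))

    def test_rejects_empty_and_zero(self):
        with pytest.raises(ValueError):
            cluster_score([])
        with pytest.raises(ValueError):
            cluster_score([0.0, 0.5])

    def test_reproduces_printed_table_scores(self):
        """Printed member P-values reproduce the published cluster scores."""
        t4 = load_fixture("T4").data
        assert round(cluster_score(t4["p"]), 2) == 16.28
        t8 = load_fixture("T8").data
        full = t8[(t8["cluster"] == 1) & (t8["fully_listed"] == 1)]
        assert round(cluster_score(full["p"]), 2) == 3.59
        t10 = load_fixture("T10").data
        c2 = t10[t10["cluster"] == 2]
        assert round(cluster_score(c2["p"]), 2) == 8.42
        # cluster 1's members are printed to 3 significant figures; the score
        # recomputes to within one unit in the last printed decimal
        c1 = t10[t10["cluster"] == 1]
        assert abs(cluster_score(c1["p"]) - 19.79) <= 0.015


def oracle_cluster_groups(tids, members, N, kappa_threshold, seed_min_size, merge_overlap):
    """Independent re-derivation: seeds by pairwise kappa, merge to fixed point."""
    seeds = set()
    for t in tids:
        grp = frozenset(
            [t] + [u for u in tids if u != t and kappa(members[t], members[u], N) >= kappa_threshold]
        )
        if len(grp) >= seed_min_size:
            seeds.add(grp)
    groups = sorted(tuple(sorted(g)) for g in seeds)
    changed = True
    while changed:
        changed = False
        for gi, gj in itertools.combinations(list(groups), 2):
            si, sj = set(gi), set(gj)
            if len(si & sj) >= merge_overlap * min(len(si), len(sj)):
                groups = sorted(set(groups) - {gi, gj} | {tuple(sorted(si | sj))})
                changed = True
                break
    return set(groups)


class TestClusterTerms:
    def _enrich(self, collection, seed=5, n=20):
        rng = np.random.default_rng(seed)
        genes = rng.choice(sorted(collection.background), n, replace=False)
        return enrich_terms(genes, collection)

    def test_no_pairs_above_threshold(self):
        coll = GeneSetCollection.from_sets(
            {
                "t1": ("a", {"g1", "g2"}),
                "t2": ("b", {"g3", "g4"}),
                "t3": ("c", {"g5", "g6"}),
            },
            background=[f"g{i}" for i in range(1, 30)],
        )
        terms = enrich_terms({"g1", "g3", "g5"}, coll)
        assert cluster_terms(terms, coll, 0.5, seed_min_size=2) == []

    def test_identical_terms_form_single_cluster(self):
        members = {"g1", "g2", "g3"}
        coll = GeneSetCollection.from_sets(
            {f"t{i}": (f"copy {i}", set(members)) for i in range(3)},
            background=[f"g{i}" for i in range(1, 40)],
        )
        terms = enrich_terms(members, coll)
        clusters = cluster_terms(terms, coll, 0.35, seed_min_size=3)
        assert len(clusters) == 1
        assert clusters[0].members == ("t0", "t1", "t2")
        assert clusters[0].score == pytest.approx(
            cluster_score(terms["ease_p"]), abs=1e-9
        )

    def test_invalid_thresholds_rejected(self, toy_collection):
        terms = self._enrich(toy_collection)
        with pytest.raises(ValueError):
            cluster_terms(terms, toy_collection, kappa_threshold=1.5)
        with pytest.raises(ValueError):
            cluster_terms(terms, toy_collection, 0.35, merge_overlap=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_fixed_point_oracle_small(self, seed):
        """<= 6 random terms: greedy output equals the exhaustive merge oracle."""
        rng = np.random.default_rng(seed)
        universe = [f"g{i:02d}" for i in range(30)]
        sets = {}
        for t in range(6):
            size = int(rng.integers(3, 12))
            sets[f"t{t}"] = (f"term {t}", set(rng.choice(universe, size, replace=False)))
        coll = GeneSetCollection.from_sets(sets, background=universe)
        gene_list = set(rng.choice(universe, 12, replace=False))
        try:
            terms = enrich_terms(gene_list, coll)
        except ValueError:
            return  # list missed the background: nothing to cluster
        if terms.empty:
            return
        members = {t: coll.members(t) for t in terms.index}
        expected = oracle_cluster_groups(
            sorted(terms.index), members, len(coll.background), 0.35, 2, 0.5
        )
        got = {
            c.members
            for c in cluster_terms(terms, coll, 0.35, seed_min_size=2, merge_overlap=0.5)
        }
        assert got == expected
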