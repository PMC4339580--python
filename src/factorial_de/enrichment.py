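"""EASE-score gene-set enrichment and kappa-based term clustering.

The EASE score is a conservative variant of the one-tailed Fisher exact test:
one gene is removed from the list-hit count before computing the
hypergeometric upper tail, which penalizes categories supported by very few
genes (a single-hit term scores exactly 1). Redundant terms are grouped by
Cohen's kappa agreement of their membership vectors over the background
universe, and each cluster is summarized by an enrichment score equal to the
mean of -log10 of its members' EASE P-values (equivalently, -log10 of their
geometric mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they live in."""

    terms: dict[str, tuple[str, frozenset]]  # id -> (description, members)
    background: frozenset

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe is empty")
        restricted = {}
        for tid, (desc, members) in self.terms.items():
            kept = frozenset(members) & self.background
            restricted[tid] = (desc, kept)
        self.terms = restricted

    @classmethod
    def from_sets(cls, sets: dict[str, tuple[str, set]], background=None) -> "GeneSetCollection":
        """Background defaults to the union of all members."""
        if background is None:
            background = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
        return cls(
            terms={t: (d, frozenset(m)) for t, (d, m) in sets.items()},
            background=frozenset(background),
        )

    def members(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """EASE P-value: Fisher exact upper tail after removing one list hit.

    k list hits among a list of n genes, against K background hits in a
    universe of N. Returns P(X >= k - 1) for X hypergeometric; k <= 1 gives 1.
    """
    if min(k, n, K, N) < 0:
        raise ValueError("all arguments must be non-negative")
    if k > min(n, K):
        raise ValueError(f"k = {k} exceeds min(n, K) = {min(n, K)}")
    if n > N or K > N:
        raise ValueError("list size and background hits cannot exceed the universe")
    if k <= 1:
        return 1.0
    # P(X >= k-1) = sf(k-2) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 2, N, K, n))


def enrich_terms(gene_list, collection: GeneSetCollection) -> pd.DataFrame:
    """EASE enrichment of every term with at least one list hit.

    Returns a DataFrame indexed by term id with columns term, k, n, K, N,
    ease_p, q (BH over the reported terms), ordered by ascending ease_p then
    term id.
    """
    from factorial_de.contrasts import bh_adjust

    genes = frozenset(gene_list)
    if not genes:
        raise ValueError("gene list is empty")
    in_bg = genes & collection.background
    if not in_bg:
        raise ValueError("gene list does not intersect the background universe")
    n = len(in_bg)
    N = len(collection.background)
    rows = []
    for tid in sorted(collection.terms):
        desc, members = collection.terms[tid]
        k = len(in_bg & members)
        if k == 0:
            continue
        rows.append(
            {
                "term": desc,
                "k": k,
                "n": n,
                "K": len(members),
                "N": N,
                "ease_p": ease_p(k, n, len(members), N),
                "term_id": tid,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "ease_p", "q"],
            index=pd.Index([], name="term_id"),
        )
    df = pd.DataFrame(rows).set_index("term_id")
    df["q"] = bh_adjust(df["ease_p"].to_numpy())
    return df.loc[sorted(df.index, key=lambda t: (df.at[t, "ease_p"], str(t)))]


def kappa(members_a, members_b, background_size: int) -> float:
    """Cohen's kappa of two binary membership vectors over the background.

    1 for identical sets (including two empty sets), <= 0 at or below chance
    agreement, -1 for a perfect complementary split.
    """
    a_set, b_set = frozenset(members_a), frozenset(members_b)
    union = a_set | b_set
    if background_size < len(union):
        raise ValueError("background smaller than the union of the two sets")
    n11 = len(a_set & b_set)
    n10 = len(a_set - b_set)
    n01 = len(b_set - a_set)
    n00 = background_size - len(union)
    N = background_size
    po = (n11 + n00) / N
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (N * N)
    if pe == 1.0:
        return 1.0  # degenerate marginals: vectors are constant and identical
    return (po - pe) / (1.0 - pe)


def cluster_score(p_values) -> float:
    """Mean of -log10(p): -log10 of the geometric mean of member P-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("cluster_score of empty input")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    return float(np.mean(-np.log10(p)))


@dataclass(frozen=True)
class EnrichmentCluster:
    """A group of agreeing terms with its geometric-mean enrichment score."""

    members: tuple[str, ...]
    score: float


def cluster_terms(
    terms: pd.DataFrame,
    collection: GeneSetCollection,
    kappa_threshold: float = 0.35,
    seed_min_size: int = 3,
    merge_overlap: float = 0.5,
) -> list[EnrichmentCluster]:
    """Greedy deterministic clustering of enriched terms by kappa agreement.

    1. Seed a candidate group per term: the term plus every term whose
       pairwise kappa with it reaches ``kappa_threshold``.
    2. Discard candidates smaller than ``seed_min_size``.
    3. Repeatedly merge any two groups sharing at least ``merge_overlap`` of
       the smaller group's members, scanning groups in lexicographic member
       order, until no merge applies.

    Each surviving group scores the mean -log10 of its members' EASE
    P-values. Clusters are returned by descending score, ties broken
    lexicographically.
    """
    if not 0.0 < kappa_threshold < 1.0:
        raise ValueError("kappa_threshold must be in (0, 1)")
    if not 0.0 < merge_overlap <= 1.0:
        raise ValueError("merge_overlap must be in (0, 1]")
    if seed_min_size < 1:
        raise ValueError("seed_min_size must be >= 1")
    tids = sorted(terms.index)
    N = len(collection.background)
    members = {t: collection.members(t) for t in tids}

    candidates = set()
    for t in tids:
        group = {t} | {
            u for u in tids if u != t and kappa(members[t], members[u], N) >= kappa_threshold
        }
        if len(group) >= seed_min_size:
            candidates.add(tuple(sorted(group)))

    groups = sorted(candidates)
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = set(groups[i]), set(groups[j])
                smaller = min(len(gi), len(gj))
                if len(gi & gj) >= merge_overlap * smaller:
                    union = tuple(sorted(gi | gj))
                    groups = sorted(set(groups) - {groups[i], groups[j]} | {union})
                    merged = True
                    break
            if merged:
                break

    clusters = [
        EnrichmentCluster(
            members=g, score=cluster_score(terms.loc[list(g), "ease_p"].to_numpy())
        )
        for g in groups
    ]
    clusters.sort(key=lambda c: (-c.score, c.members))
    return clusters
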