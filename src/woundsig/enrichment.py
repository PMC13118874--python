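"""Over-representation analysis of wound signatures with kappa term clustering.

Each gene-set term is tested against a query gene list with the one-sided
hypergeometric tail (the standard ORA test), q-values follow Benjamini-
Hochberg, and a term is significant when its overlap exceeds 3 genes with
p < 0.01. Significant terms are then grouped by Cohen's kappa agreement of
their membership indicator vectors over the universe, single-linkage at
kappa > 0.3, and each cluster is summarized by its lowest-p representative —
the usual redundancy-reduction step for term lists.

The universe defaults to the genes tested at the differential-expression
stage, the defensible background for an expression study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ENRICH_MIN_COUNT_EXCLUSIVE = 3  # overlap <= 3 not significant
ENRICH_P = 0.01
KAPPA_THRESHOLD = 0.3


def ora_hypergeometric(
    query_set: set, term_set: set, universe_size: int
) -> tuple[int, float]:
    """Overlap count and one-sided hypergeometric enrichment p-value.

    p = P(X >= overlap) for X ~ Hypergeom(N=universe, K=|term|, n=|query|).
    """
    query_set, term_set = set(query_set), set(term_set)
    if not query_set:
        raise ValueError("ora: empty query set")
    if universe_size < len(query_set | term_set):
        raise ValueError("universe smaller than query ∪ term")
    overlap = len(query_set & term_set)
    p = float(
        stats.hypergeom.sf(overlap - 1, universe_size, len(term_set), len(query_set))
    )
    return overlap, min(max(p, 0.0), 1.0)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_qvalues: empty input")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def kappa_similarity(term_a: set, term_b: set, universe_size: int) -> float:
    """Cohen's kappa of two sets' membership indicators over the universe."""
    a_set, b_set = set(term_a), set(term_b)
    n = universe_size
    if n < len(a_set | b_set):
        raise ValueError("universe smaller than the union of the two sets")
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    d = n - a - b - c
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EnrichmentResult:
    """Full ORA output: one row per term with cluster assignment."""

    table: pd.DataFrame
    universe_size: int


def run_ora(
    query_set: set,
    collections: dict[str, list[str]],
    universe: set,
    min_count_exclusive: int = ENRICH_MIN_COUNT_EXCLUSIVE,
    p_threshold: float = ENRICH_P,
    kappa_threshold: float = KAPPA_THRESHOLD,
    kappa_mode: str = "universe",
) -> EnrichmentResult:
    """Test every term, BH-adjust, flag significance and cluster the hits.

    Term genes outside the universe are ignored (standard background
    restriction). ``kappa_mode="universe"`` computes kappa on full membership
    vectors over the universe; ``"query"`` restricts membership to each term's
    overlap with the query (closer to how enrichment portals cluster terms,
    but dependent on the query).
    """
    universe = set(universe)
    query = set(query_set) & universe
    if not query:
        raise ValueError("query has no genes in the universe")
    n = len(universe)
    rows = []
    restricted: dict[str, set] = {}
    for name in sorted(collections):
        term = set(collections[name]) & universe
        if not term:
            continue
        restricted[name] = term
        overlap, p = ora_hypergeometric(query, term, n)
        rows.append(
            {"term": name, "overlap_count": overlap, "set_size": len(term), "p_hyper": p}
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q_bh"] = bh_qvalues(table["p_hyper"].values)
    table["passed"] = (table["overlap_count"] > min_count_exclusive) & (
        table["p_hyper"] < p_threshold
    )

    table["cluster_id"] = -1
    table["representative"] = False
    significant = list(table.index[table["passed"]])
    if significant:
        members = {
            name: (
                restricted[name]
                if kappa_mode == "universe"
                else restricted[name] & query
            )
            for name in significant
        }
        clusters = cluster_terms(
            members,
            table.loc[significant, "p_hyper"].to_dict(),
            n if kappa_mode == "universe" else len(query),
            kappa_threshold=kappa_threshold,
        )
        for name, (cid, is_rep) in clusters.items():
            table.loc[name, "cluster_id"] = cid
            table.loc[name, "representative"] = is_rep
    return EnrichmentResult(table=table, universe_size=n)


def cluster_terms(
    members: dict[str, set],
    p_values: dict[str, float],
    universe_size: int,
    kappa_threshold: float = KAPPA_THRESHOLD,
) -> dict[str, tuple[int, bool]]:
    """Single-linkage clustering of terms at kappa > threshold.

    Single linkage with a hard cut is exactly the connected components of the
    graph joining term pairs whose kappa exceeds the threshold, so clusters
    are found by union-find — deterministic regardless of input order. Cluster
    ids are assigned in order of the sorted id of each cluster's first term;
    the representative is the lowest-p member (ties by term id).
    """
    names = sorted(members)
    if not names:
        raise ValueError("no terms to cluster")
    parent = {name: name for name in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if kappa_similarity(members[a], members[b], universe_size) > kappa_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for name in names:
        groups.setdefault(find(name), []).append(name)
    out: dict[str, tuple[int, bool]] = {}
    for cid, root in enumerate(sorted(groups), start=1):
        group = groups[root]
        rep = min(group, key=lambda t: (p_values[t], t))
        for name in group:
            out[name] = (cid, name == rep)
    return out
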