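"""KS connectivity scoring of wound signatures against a perturbagen reference.

Each reference signature ranks the gene universe by its differential z-score
(descending). The classic unweighted connectivity-map enrichment statistic is
computed for the query's up-tags and down-tags separately:

    a  = max_j ( j/t - V(j)/n )
    b  = max_j ( V(j)/n - (j-1)/t )
    es = a if a > b else -b

where t is the tag count, n the universe size and V(j) the rank of the j-th
tag. The combined connectivity score is (es_up - es_down)/2 when the two
enrichment scores have opposite signs and 0 otherwise; a negative score means
the perturbagen shifts the query's up-genes down and down-genes up, i.e. it is
predicted to reverse the queried transcriptional state.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from woundsig.containers import ReferenceSignatureSet, WoundSignature
from woundsig.signatures import DEFAULT_TAG_CAP

logger = logging.getLogger(__name__)


def ks_enrichment(tag_positions, n_total: int) -> float:
    """Unweighted KS enrichment score of a tag set within a ranked list.

    ``tag_positions`` are distinct 1-based ranks in ``[1, n_total]``. The score
    lies in [-1, 1); positive when tags concentrate at the top of the ranking
    (-1 is attained exactly when the whole tag set sits at the bottom). A tag
    set covering the whole list leaves the statistic undefined.
    """
    v = np.asarray(sorted(tag_positions), dtype=np.int64)
    t = v.size
    if t == 0:
        raise ValueError("ks_enrichment: empty tag set")
    if t >= n_total:
        raise ValueError("ks_enrichment: tag set covers the whole ranked list")
    if v[0] < 1 or v[-1] > n_total or np.unique(v).size != t:
        raise ValueError("tag positions must be distinct integers in [1, n_total]")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n_total))
    b = float(np.max(v / n_total - (j - 1) / t))
    return a if a > b else -b


def rank_reference_column(z: np.ndarray, gene_order: np.ndarray) -> np.ndarray:
    """Permutation ranking a column by z descending, ties by gene id ascending.

    ``gene_order[i]`` is the lexicographic rank of gene i's id; returns an
    array ``rank`` with ``rank[i]`` = 0-based position of gene i in the ranked
    list.
    """
    order = np.lexsort((gene_order, -z))
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return rank


class _QueryIndex:
    """Query tag sets resolved to row indices of a reference gene universe."""

    def __init__(
        self,
        query: WoundSignature,
        ref_genes: pd.Index,
        tag_cap: int = DEFAULT_TAG_CAP,
        ortholog_map: dict[str, str] | None = None,
    ):
        capped = query.capped(tag_cap)
        lookup = {str(g).upper(): i for i, g in enumerate(ref_genes)}
        if ortholog_map:
            translate = {k.upper(): v for k, v in ortholog_map.items()}
        else:
            translate = {}

        def resolve(genes: list[str]) -> np.ndarray:
            idx = []
            for g in genes:
                key = str(g).upper()
                key = str(translate.get(key, key)).upper()
                if key in lookup:
                    idx.append(lookup[key])
            return np.asarray(idx, dtype=np.int64)

        self.up_idx = resolve(capped.up_genes)
        self.down_idx = resolve(capped.down_genes)
        self.n_query_up = len(capped.up_genes)
        self.n_query_down = len(capped.down_genes)
        dropped = (self.n_query_up - self.up_idx.size) + (
            self.n_query_down - self.down_idx.size
        )
        if dropped:
            logger.info(
                "query %s: %d tag genes absent from the reference universe",
                query.timepoint,
                dropped,
            )


def combine_scores(es_up: float, es_down: float) -> float:
    """Canonical combined connectivity score: zero when the signs agree."""
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def score_signature(
    query: WoundSignature,
    column: pd.Series,
    tag_cap: int = DEFAULT_TAG_CAP,
    ortholog_map: dict[str, str] | None = None,
) -> dict:
    """Score a single reference signature column against a wound query."""
    qi = _QueryIndex(query, column.index, tag_cap=tag_cap, ortholog_map=ortholog_map)
    gene_order = np.argsort(np.argsort(column.index.values.astype(str)))
    rank = rank_reference_column(column.values.astype(float), gene_order)
    return _score_from_ranks(qi, rank, column.size)


def _score_from_ranks(qi: _QueryIndex, rank: np.ndarray, n: int) -> dict:
    matched_up, matched_down = qi.up_idx.size, qi.down_idx.size
    if matched_up == 0 or matched_down == 0:
        return {
            "es_up": np.nan,
            "es_down": np.nan,
            "score": np.nan,
            "n_matched_up": matched_up,
            "n_matched_down": matched_down,
            "unmatched": True,
        }
    es_up = ks_enrichment(rank[qi.up_idx] + 1, n)
    es_down = ks_enrichment(rank[qi.down_idx] + 1, n)
    return {
        "es_up": es_up,
        "es_down": es_down,
        "score": combine_scores(es_up, es_down),
        "n_matched_up": matched_up,
        "n_matched_down": matched_down,
        "unmatched": False,
    }


def score_all(
    query: WoundSignature,
    reference: ReferenceSignatureSet,
    tag_cap: int = DEFAULT_TAG_CAP,
    ortholog_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score every reference signature; one row per signature column.

    Rows with no matched query gene in either direction are flagged
    ``unmatched`` and carry NaN scores (callers exclude them from ranking).
    """
    z = reference.z
    qi = _QueryIndex(query, z.index, tag_cap=tag_cap, ortholog_map=ortholog_map)
    gene_order = np.argsort(np.argsort(z.index.values.astype(str)))
    n = z.shape[0]
    rows = []
    zvals = z.values
    for k, sig_id in enumerate(z.columns):
        rank = rank_reference_column(zvals[:, k], gene_order)
        row = _score_from_ranks(qi, rank, n)
        row["signature_id"] = sig_id
        row["pert_id"] = reference.perturbagen_of(sig_id)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("signature_id")
    n_unmatched = int(out["unmatched"].sum())
    if n_unmatched:
        logger.warning("%d signatures had no matched query genes", n_unmatched)
    return out[["pert_id", "es_up", "es_down", "score", "n_matched_up", "n_matched_down", "unmatched"]]


def permutation_null(
    query_sizes: tuple[int, int],
    column: pd.Series,
    observed_score: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical negative-tail p for one signature by random tag sets.

    Draws ``n_perm`` random up/down tag sets of the query's sizes from the
    column's gene universe and returns
    ``p = (1 + #{null score <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("permutation_null: n_perm must be >= 100")
    t_up, t_down = query_sizes
    n = column.size
    rng = np.random.default_rng(seed)
    gene_order = np.argsort(np.argsort(column.index.values.astype(str)))
    rank = rank_reference_column(column.values.astype(float), gene_order)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        up_pos = rank[perm[:t_up]] + 1
        down_pos = rank[perm[t_up : t_up + t_down]] + 1
        es_u = ks_enrichment(up_pos, n)
        es_d = ks_enrichment(down_pos, n)
        if combine_scores(es_u, es_d) <= observed_score:
            hits += 1
    return (1 + hits) / (n_perm + 1)
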