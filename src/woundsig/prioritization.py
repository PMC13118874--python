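"""Candidate-compound prioritization from connectivity scores.

A perturbagen is promising when its signatures recur among the K most-negative
connectivity scores more often than chance. For each perturbagen we count its
signatures inside the top-K negative set (``freq_topk``), test over-representation
with a one-sided Fisher exact test on the 2x2 table

    a = freq_topk              b = total_sigs - freq_topk
    c = topk_size - freq_topk  d = grand_total - total_sigs - c

(margins over all scored signatures), and keep compounds with ``freq > 3`` and
``p < 0.05``, ranked by frequency then p. Mechanism-of-action and clinical
phase come from a perturbagen annotation table with an "unknown" fallback.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from woundsig.containers import ReferenceSignatureSet

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 1000
FREQ_MIN_EXCLUSIVE = 3  # freq <= 3 excluded
FISHER_ALPHA = 0.05  # p >= 0.05 excluded


def topk_membership(connectivity: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """Ids of the k most-negative scored signatures (ties by signature id).

    Only negative scores are eligible; if fewer than k signatures score
    negative, all of them are returned. Unmatched/NaN rows are skipped.
    """
    usable = connectivity[~connectivity["score"].isna() & (connectivity["score"] < 0)]
    if usable.empty:
        warnings.warn("no negative connectivity scores; top-K set is empty")
        return []
    ordered = usable.iloc[
        np.lexsort((usable.index.values.astype(str), usable["score"].values))
    ]
    return list(ordered.index[:k])


def fisher_enrichment(freq, total_sigs, topk_size: int, grand_total: int):
    """One-sided (enrichment) Fisher exact test for top-K over-representation.

    ``freq`` and ``total_sigs`` may be scalars or equal-length arrays. Returns
    ``(p, odds_ratio)`` with the hypergeometric tail p = P(X >= freq) and the
    sample odds ratio ad/bc (+inf when bc = 0).
    """
    a = np.asarray(freq, dtype=np.int64)
    tot = np.broadcast_to(np.asarray(total_sigs, dtype=np.int64), a.shape)
    b = tot - a
    c = topk_size - a
    d = grand_total - tot - c
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("inconsistent 2x2 margins (negative cell)")
    # X ~ Hypergeom(N=grand_total, K=total_sigs, n=topk_size)
    p = stats.hypergeom.sf(a - 1, grand_total, tot, topk_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(b * c == 0, np.inf, a * d / np.where(b * c == 0, 1, b * c))
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(freq) or np.ndim(freq) == 0:
        return float(p), float(odds)
    return p, odds


def rank_candidates(
    connectivity: pd.DataFrame,
    pert_meta: pd.DataFrame | None = None,
    k: int = DEFAULT_TOP_K,
    freq_min_exclusive: int = FREQ_MIN_EXCLUSIVE,
    fisher_alpha: float = FISHER_ALPHA,
) -> pd.DataFrame:
    """Build the ranked candidate table for one query's connectivity results.

    Every perturbagen with at least one signature in the top-K negative set
    appears; ``passed_filters`` marks those with ``freq > freq_min_exclusive``
    and ``fisher_p < fisher_alpha`` (both boundaries exclusive, i.e. freq <= 3
    and p >= 0.05 are excluded). Ranks 1..n are assigned over all rows by
    frequency descending, Fisher p ascending, then perturbagen id.
    """
    scored = connectivity[~connectivity["unmatched"]]
    grand_total = int(len(scored))
    top_set = topk_membership(scored, k=k)
    topk_size = len(top_set)
    top_perts = scored.loc[top_set, "pert_id"]

    freq = top_perts.value_counts()
    totals = scored["pert_id"].value_counts()
    perts = sorted(freq.index)
    if not perts:
        return pd.DataFrame(
            columns=[
                "freq_topk", "total_sigs", "fisher_p", "odds_ratio",
                "moa", "phase", "rank", "passed_filters",
            ]
        )
    freq_arr = freq.loc[perts].values
    tot_arr = totals.loc[perts].values
    p, odds = fisher_enrichment(freq_arr, tot_arr, topk_size, grand_total)
    table = pd.DataFrame(
        {
            "freq_topk": freq_arr,
            "total_sigs": tot_arr,
            "fisher_p": p,
            "odds_ratio": odds,
        },
        index=pd.Index(perts, name="pert_id"),
    )
    table["moa"] = _annotate(table.index, pert_meta, "moa")
    table["phase"] = _annotate(table.index, pert_meta, "phase")
    order = np.lexsort(
        (table.index.values.astype(str), table["fisher_p"].values, -table["freq_topk"].values)
    )
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    table["passed_filters"] = (table["freq_topk"] > freq_min_exclusive) & (
        table["fisher_p"] < fisher_alpha
    )
    return table


def _annotate(perts: pd.Index, pert_meta: pd.DataFrame | None, column: str) -> list[str]:
    if pert_meta is None or column not in pert_meta.columns:
        return ["unknown"] * len(perts)
    return [
        str(pert_meta.loc[p, column]) if p in pert_meta.index else "unknown"
        for p in perts
    ]


def aggregate_across_conditions(
    per_timepoint: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Union report over timepoints: one row per candidate that passed anywhere.

    Frequencies are not pooled across timepoints; each candidate row carries
    the timepoints at which it passed, its best (lowest) Fisher p and its best
    rank.
    """
    if not per_timepoint:
        raise ValueError("no candidate tables to aggregate")
    rows: dict[str, dict] = {}
    for tp in sorted(per_timepoint):
        table = per_timepoint[tp]
        passed = table[table["passed_filters"]]
        for pert, row in passed.iterrows():
            entry = rows.setdefault(
                pert,
                {
                    "timepoints": [],
                    "best_rank": np.inf,
                    "best_fisher_p": np.inf,
                    "moa": row["moa"],
                    "phase": row["phase"],
                },
            )
            entry["timepoints"].append(tp)
            entry["best_rank"] = min(entry["best_rank"], int(row["rank"]))
            entry["best_fisher_p"] = min(entry["best_fisher_p"], float(row["fisher_p"]))
    out = pd.DataFrame.from_dict(rows, orient="index")
    if not out.empty:
        out.index.name = "pert_id"
        out["timepoints"] = out["timepoints"].map(lambda tps: ",".join(tps))
        out = out.iloc[
            np.lexsort(
                (
                    out.index.values.astype(str),
                    out["best_fisher_p"].values,
                    out["best_rank"].values,
                )
            )
        ]
    return out
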