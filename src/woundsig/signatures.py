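"""Wound-specific signature extraction and descriptive exports.

The wound-only DEG set (WsDEG) at a timepoint is the Venn exclusion
``DEG(AW) \\ (DEG(N) ∪ DEG(A))`` computed on gene identity: a gene
differentially expressed in the wounding arm is dropped if it is also called in
the no-treatment or anesthesia-only arm at the same timepoint, regardless of
direction. The survivors are split into up/down query tag sets by the sign of
the AW fold change and ordered by |log2FC| descending so they can be truncated
to a connectivity tag-set cap reproducibly.

Also here: the data-only descriptive exports (z-score heatmap rows, Pearson
sample-correlation matrix, classical MDS coordinates, volcano table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from woundsig.containers import DegTable, ExpressionMatrix, WoundSignature

#: Default per-direction tag-set cap applied before connectivity scoring.
DEFAULT_TAG_CAP = 150


def extract_wsdegs(
    deg_aw: DegTable,
    deg_n: DegTable,
    deg_a: DegTable,
    direction_aware: bool = False,
) -> WoundSignature:
    """Venn-exclude N/A DEGs from the AW DEG set at one timepoint.

    With ``direction_aware=True`` a gene is only excluded when it is called in
    N or A *with the same direction* as in AW; the default excludes on gene
    identity alone. Provenance records the bookkeeping identity
    ``n_wsdeg + n_excluded_overlap = n_deg_aw``.
    """
    tps = {deg_aw.timepoint, deg_n.timepoint, deg_a.timepoint}
    if len(tps) != 1:
        raise ValueError(f"mixed timepoints in WsDEG extraction: {sorted(tps)}")
    if (deg_aw.intervention, deg_n.intervention, deg_a.intervention) != ("AW", "N", "A"):
        raise ValueError(
            "extract_wsdegs expects DEG tables for the AW, N and A arms in that order"
        )
    aw_called = deg_aw.table[deg_aw.table["is_deg"]]
    if direction_aware:
        excluded_ids = set()
        for other in (deg_n, deg_a):
            called = other.table[other.table["is_deg"]]
            for gene, direction in called["direction"].items():
                if gene in aw_called.index and aw_called.loc[gene, "direction"] == direction:
                    excluded_ids.add(gene)
    else:
        excluded_ids = (deg_n.deg_genes | deg_a.deg_genes) & set(aw_called.index)

    kept = aw_called.drop(index=sorted(excluded_ids))
    # order by effect magnitude, ties by gene id, so truncation is stable
    kept = kept.iloc[
        np.lexsort((kept.index.values, -kept["log2fc"].abs().values))
    ]
    up = [g for g in kept.index if kept.loc[g, "log2fc"] > 0]
    down = [g for g in kept.index if kept.loc[g, "log2fc"] < 0]
    n_discordant = int(
        sum(
            1
            for g in excluded_ids
            if _direction_of(deg_aw, g) not in (_direction_of(deg_n, g), _direction_of(deg_a, g))
        )
    )
    return WoundSignature(
        timepoint=deg_aw.timepoint,
        up_genes=up,
        down_genes=down,
        provenance={
            "n_deg_aw": int(len(aw_called)),
            "n_excluded_overlap": int(len(excluded_ids)),
            "n_wsdeg": int(len(kept)),
            "n_up": len(up),
            "n_down": len(down),
            "n_excluded_discordant_direction": n_discordant,
            "direction_aware": direction_aware,
        },
    )


def _direction_of(deg: DegTable, gene: str) -> str:
    if gene in deg.table.index and deg.table.loc[gene, "is_deg"]:
        return str(deg.table.loc[gene, "direction"])
    return "none"


def signature_matrices(
    expr: ExpressionMatrix, signature: WoundSignature, sample_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores of signature genes for heatmap export.

    Each row is centred and scaled by its sample (n-1) standard deviation
    across the selected samples. Rows with zero variance are emitted as zeros
    and flagged. Returns ``(zscores, zero_sd_flags)``.
    """
    cols = list(expr.values.columns) if sample_ids is None else list(sample_ids)
    if len(cols) < 2:
        raise ValueError("z-score rows need at least 2 samples (sd undefined otherwise)")
    genes = [g for g in [*signature.up_genes, *signature.down_genes] if g in expr.values.index]
    sub = expr.values.loc[genes, cols]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    safe_sd = sd.replace(0, 1.0)
    z = sub.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[flat] = 0.0
    return z, flat


def sample_similarity(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlation of samples plus 2-D classical MDS.

    MDS embeds the distance ``1 - r`` by classical scaling (eigendecomposition
    of the double-centred squared-distance matrix); axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    vals = expr.values
    if vals.shape[1] < 3:
        raise ValueError("sample similarity needs at least 3 samples")
    sds = vals.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"sample {bad!r} is constant; correlation undefined")
    corr = vals.corr(method="pearson")
    dist = 1.0 - corr.values
    coords = classical_mds(dist, n_components=2)
    mds = pd.DataFrame(coords, index=vals.columns, columns=["MDS1", "MDS2"])
    return corr, mds


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    # deterministic axis orientation
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def volcano_data(deg: DegTable) -> pd.DataFrame:
    """Data-only volcano export: gene, log2fc, -log10 p, call flags."""
    t = deg.table
    return pd.DataFrame(
        {
            "log2fc": t["log2fc"],
            "neg_log10_p": -np.log10(t["p_raw"]),
            "is_deg": t["is_deg"],
            "is_top_deg": t["is_top_deg"],
            "direction": t["direction"],
        },
        index=t.index,
    )
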