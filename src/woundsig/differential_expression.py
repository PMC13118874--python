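"""Per-timepoint differential expression against baseline, and tumor burden.

Each post-intervention subgroup (N, A, AW at T1/T2/T3) is contrasted against
the baseline tumors with a two-sided Welch t-test on log2(TPM-UQ + 1) values;
the log2 fold change is the difference of group means of log2 expression
(a geometric-mean ratio). Two DEG tiers are called on |log2FC| and the raw
p-value; Storey q-values are computed and reported alongside but are not used
for calling (with these group sizes FDR adjustment is expected to retain
nothing, so calling is exploratory on raw p).

Tumor burden between intervention arms is compared with a pooled-variance
Student t-test per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from woundsig.containers import BASELINE, DegTable, ExpressionMatrix, INTERVENTIONS, TIMEPOINTS

# Two-tier DEG thresholds: |FC| >= 1.5 and raw p <= 0.05 for the main tier,
# |log2FC| >= 4 (16-fold) and raw p <= 0.01 for the high-magnitude tier.
DEG_LOG2FC = 0.58
DEG_P = 0.05
TOP_DEG_LOG2FC = 4.0
TOP_DEG_P = 0.01


@dataclass(frozen=True)
class ContrastSpec:
    """One group-vs-baseline contrast: a timepoint and an intervention arm."""

    timepoint: str
    intervention: str
    reference: str = BASELINE

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.intervention not in INTERVENTIONS:
            raise ValueError(f"unknown intervention {self.intervention!r}")


def _group_columns(expr: ExpressionMatrix, contrast: ContrastSpec) -> tuple[list[str], list[str]]:
    meta = expr.samples
    in_group = (meta["timepoint"] == contrast.timepoint) & (
        meta["intervention"] == contrast.intervention
    )
    in_ref = meta["timepoint"] == contrast.reference
    group = [c for c in expr.values.columns if c in meta.index[in_group]]
    ref = [c for c in expr.values.columns if c in meta.index[in_ref]]
    label = f"{contrast.timepoint}_{contrast.intervention}"
    if len(group) < 2:
        raise ValueError(f"contrast group {label} has {len(group)} samples; need >= 2")
    if len(ref) < 2:
        raise ValueError(f"reference group {contrast.reference} has {len(ref)} samples; need >= 2")
    return group, ref


def test_contrast(
    expr: ExpressionMatrix,
    contrast: ContrastSpec,
    fc_mode: str = "mean-of-logs",
) -> DegTable:
    """Welch t-test per gene for one subgroup against baseline.

    Parameters
    ----------
    expr
        log2-TPM-UQ expression matrix.
    contrast
        Timepoint/intervention pair to test against baseline.
    fc_mode
        ``"mean-of-logs"`` (default): log2FC = mean(log2 group) - mean(log2
        base). ``"log-of-means"``: log2 of the ratio of arithmetic means on the
        linear scale (2**log2expr - 1).

    Genes with zero variance in both groups get ``p_raw = 1`` with the fold
    change still computed from the means.
    """
    if expr.normalization_tag != "log2-TPM-UQ":
        raise ValueError(
            f"test_contrast expects log2-TPM-UQ values, got {expr.normalization_tag!r}"
        )
    if not np.isfinite(expr.values.values).all():
        raise ValueError("expression matrix contains non-finite values")
    group_cols, ref_cols = _group_columns(expr, contrast)
    g = expr.values[group_cols].values
    r = expr.values[ref_cols].values

    if fc_mode == "mean-of-logs":
        log2fc = g.mean(axis=1) - r.mean(axis=1)
    elif fc_mode == "log-of-means":
        lin_g = np.maximum(2.0**g - 1.0, 0.0).mean(axis=1)
        lin_r = np.maximum(2.0**r - 1.0, 0.0).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2((lin_g + 1.0) / (lin_r + 1.0))
    else:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger scipy's precision-loss warning; they are
        # assigned p = 1 explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_raw = stats.ttest_ind(g, r, axis=1, equal_var=False)
    zero_var = (g.var(axis=1) == 0) & (r.var(axis=1) == 0)
    p_raw = np.where(zero_var, 1.0, p_raw)
    # identical constant groups also yield nan from a 0/0 t statistic
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p_raw},
        index=expr.values.index,
    )
    table["q_storey"] = storey_qvalues(table["p_raw"].values)
    deg = DegTable(table=table, timepoint=contrast.timepoint, intervention=contrast.intervention)
    return call_degs(deg)


def call_degs(
    deg: DegTable,
    deg_log2fc: float = DEG_LOG2FC,
    deg_p: float = DEG_P,
    top_log2fc: float = TOP_DEG_LOG2FC,
    top_p: float = TOP_DEG_P,
) -> DegTable:
    """Apply the two DEG tiers; boundary comparisons are inclusive (>=, <=)."""
    t = deg.table
    abs_fc = t["log2fc"].abs()
    t["is_deg"] = (abs_fc >= deg_log2fc) & (t["p_raw"] <= deg_p)
    t["is_top_deg"] = (abs_fc >= top_log2fc) & (t["p_raw"] <= top_p)
    t["direction"] = np.where(
        t["is_deg"] & (t["log2fc"] > 0), "up", np.where(t["is_deg"], "down", "none")
    )
    return deg


def storey_pi0(p_values: np.ndarray) -> float:
    """Estimate the null proportion pi0 on the lambda grid 0.05..0.95.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)); a least-squares cubic is
    fit over the grid and evaluated at the largest lambda, then clipped to
    (0, 1]. With fewer than 100 p-values the grid estimate is unstable and
    pi0 is fixed at 1 (the conservative choice).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_grid, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Storey q-values: q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).

    Ties in p share their average rank, so equal p-values always receive equal
    q-values. Output is in the input order, in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("storey_qvalues: empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = storey_pi0(p)
    ranks = stats.rankdata(p, method="average")
    raw = pi0 * m * p / ranks
    order = np.argsort(p, kind="mergesort")  # ascending p
    q = np.empty(m)
    running = np.inf
    for idx in order[::-1]:  # from largest p downward: cumulative minimum
        running = min(running, raw[idx])
        q[idx] = running
    return np.clip(q, 0.0, 1.0)


def compare_tumor_burden(weights: pd.DataFrame) -> pd.DataFrame:
    """Pooled-variance Student t-tests between intervention arms per timepoint.

    ``weights`` has columns ``timepoint``, ``intervention``, ``weight``. The
    pairs tested are AW vs N, AW vs A and A vs N at each timepoint present.
    Identical groups with zero pooled variance give p = 1; zero pooled variance
    with different means is degenerate and raises.
    """
    required = {"timepoint", "intervention", "weight"}
    if not required <= set(weights.columns):
        raise ValueError(f"weights table needs columns {sorted(required)}")
    rows = []
    for tp in sorted(weights["timepoint"].unique()):
        sub = weights[weights["timepoint"] == tp]
        groups = {
            iv: sub.loc[sub["intervention"] == iv, "weight"].values
            for iv in INTERVENTIONS
        }
        for a, b in (("AW", "N"), ("AW", "A"), ("A", "N")):
            x, y = groups[a], groups[b]
            if len(x) < 2 or len(y) < 2:
                continue
            sp2 = (
                (len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)
            ) / (len(x) + len(y) - 2)
            if sp2 == 0:
                if np.isclose(x.mean(), y.mean()):
                    t_stat, p = 0.0, 1.0
                else:
                    raise ValueError(
                        f"{tp} {a} vs {b}: zero pooled variance with unequal means"
                    )
            else:
                t_stat, p = stats.ttest_ind(x, y, equal_var=True)
            rows.append(
                {
                    "timepoint": tp,
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(x),
                    "n_b": len(y),
                    "mean_a": x.mean(),
                    "mean_b": y.mean(),
                    "t": float(t_stat),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def run_all_contrasts(expr: ExpressionMatrix) -> dict[str, dict[str, DegTable]]:
    """All nine subgroup-vs-baseline contrasts, keyed [timepoint][intervention]."""
    out: dict[str, dict[str, DegTable]] = {}
    for tp in TIMEPOINTS:
        out[tp] = {}
        for iv in INTERVENTIONS:
            out[tp][iv] = test_contrast(expr, ContrastSpec(tp, iv))
    return out


def write_deg_table(deg: DegTable, path) -> None:
    out = deg.table.copy()
    out.insert(0, "contrast", deg.contrast)
    out.to_csv(path, sep="\t", index_label="gene_id")
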