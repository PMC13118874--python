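"""TPM and upper-quartile (TPM-UQ) normalization.

TPM rescales each sample's counts by gene length (length-normalized rate
``count / length_kb``) and library depth so each column sums to one million.
Upper-quartile scaling then removes residual per-sample composition effects by
dividing each sample by the 75th percentile of its nonzero TPM values; the
geometric mean of those percentiles is multiplied back in so the output stays
on a TPM-like scale. Downstream testing is done on log2(TPM-UQ + pseudocount).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from woundsig.containers import CountExperiment, ExpressionMatrix

MIN_NONZERO_FOR_UQ = 4


def counts_to_tpm(experiment: CountExperiment) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per sample: ``rate_g = count_g / length_kb_g``; ``TPM_g = 1e6 * rate_g /
    sum(rates)``. Columns sum to 1e6 exactly (up to float rounding).

    Raises
    ------
    ValueError
        If any sample column is all zero (its TPM is undefined).
    """
    lengths_kb = experiment.gene_lengths.values.astype(float) / 1e3
    rates = experiment.counts.values / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = experiment.counts.columns[zero][0]
        raise ValueError(f"sample {bad!r} has no reads; TPM undefined")
    tpm = 1e6 * rates / totals
    return ExpressionMatrix(
        values=pd.DataFrame(
            tpm, index=experiment.counts.index, columns=experiment.counts.columns
        ),
        normalization_tag="TPM",
        samples=experiment.samples,
    )


def upper_quartile_scale(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Apply per-sample upper-quartile scaling to a TPM matrix.

    Each sample is divided by the 75th percentile of its nonzero TPM values
    (linear-interpolation percentile) and the matrix is re-centered by the
    geometric mean of those percentiles, so a sample identical to another up to
    a scale factor becomes equal to it. Scale factors are recorded for audit.
    """
    if tpm.normalization_tag != "TPM":
        raise ValueError(
            f"upper-quartile scaling expects a TPM matrix, got {tpm.normalization_tag!r}"
        )
    uq = {}
    for sample in tpm.values.columns:
        col = tpm.values[sample].values
        nonzero = col[col > 0]
        if nonzero.size < MIN_NONZERO_FOR_UQ:
            raise ValueError(
                f"sample {sample!r} has {nonzero.size} nonzero genes; "
                f"need >= {MIN_NONZERO_FOR_UQ} for a stable upper quartile"
            )
        uq[sample] = float(np.percentile(nonzero, 75))
    uq = pd.Series(uq)
    center = float(np.exp(np.mean(np.log(uq.values))))
    factors = uq / center
    scaled = tpm.values / factors
    return ExpressionMatrix(
        values=scaled,
        normalization_tag="TPM-UQ",
        samples=tpm.samples,
        scale_factors=factors,
    )


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); expects a TPM-UQ (or TPM) matrix."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if (matrix.values.values < 0).any():
        raise ValueError("log transform expects non-negative values")
    return ExpressionMatrix(
        values=np.log2(matrix.values + pseudocount),
        normalization_tag="log2-TPM-UQ",
        samples=matrix.samples,
        scale_factors=matrix.scale_factors,
    )


def normalize(experiment: CountExperiment, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Full normalization chain: counts -> TPM -> TPM-UQ -> log2."""
    return log_transform(upper_quartile_scale(counts_to_tpm(experiment)), pseudocount)
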