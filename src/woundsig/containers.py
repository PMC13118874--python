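"""In-memory containers shared across pipeline stages.

Matrices are pandas DataFrames with gene ids on the row index and sample (or
signature) ids on the columns; metadata tables are DataFrames indexed by the
entity id. Containers validate their structural invariants on construction so
that downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("T1", "T2", "T3")
INTERVENTIONS = ("N", "A", "AW")
BASELINE = "Base"
SUBGROUPS = (BASELINE,) + tuple(
    f"{tp}_{iv}" for tp in TIMEPOINTS for iv in INTERVENTIONS
)

#: Per-gene planted effect classes used by the simulator and recovery tests.
GENE_CLASSES = ("progression", "anesthesia", "wound_up", "wound_down", "null")


@dataclass
class CountExperiment:
    """Raw gene-level counts with gene lengths and the sample design.

    Attributes
    ----------
    counts : DataFrame
        gene x sample non-negative integer matrix.
    gene_lengths : Series
        Gene length in bp, indexed like ``counts``; strictly positive.
    samples : DataFrame
        One row per sample with columns ``timepoint`` (Base/T1/T2/T3) and
        ``intervention`` (N/A/AW; baseline samples carry ``intervention`` "Base").
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()]
            raise ValueError(f"genes without a length: {list(missing[:5])}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        unlabeled = set(self.counts.columns) - set(self.samples.index)
        if unlabeled:
            raise ValueError(f"samples without a design label: {sorted(unlabeled)[:5]}")

    def subgroup(self, label: str) -> list[str]:
        """Sample ids belonging to a subgroup label such as ``Base`` or ``T2_AW``."""
        if label == BASELINE:
            mask = self.samples["timepoint"] == BASELINE
        else:
            tp, iv = label.split("_")
            mask = (self.samples["timepoint"] == tp) & (
                self.samples["intervention"] == iv
            )
        return [s for s in self.counts.columns if s in self.samples.index[mask]]


@dataclass
class ExpressionMatrix:
    """A normalized expression matrix with its provenance tag.

    ``normalization_tag`` is one of ``TPM``, ``TPM-UQ`` or ``log2-TPM-UQ``;
    ``scale_factors`` records the per-sample divisors applied by upper-quartile
    scaling for audit.
    """

    values: pd.DataFrame
    normalization_tag: str
    samples: pd.DataFrame
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.normalization_tag not in ("TPM", "TPM-UQ", "log2-TPM-UQ"):
            raise ValueError(f"unknown normalization tag {self.normalization_tag!r}")
        if (self.values.values < 0).any() and self.normalization_tag != "log2-TPM-UQ":
            raise ValueError("expression values must be non-negative")


@dataclass
class DegTable:
    """Per-gene differential-expression results for one contrast vs baseline.

    ``table`` columns: log2fc, p_raw, q_storey, is_deg, is_top_deg, direction
    (up/down/none), indexed by gene id.
    """

    table: pd.DataFrame
    timepoint: str
    intervention: str

    @property
    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])

    @property
    def contrast(self) -> str:
        return f"{self.timepoint}_{self.intervention}_vs_{BASELINE}"


@dataclass
class WoundSignature:
    """Wound-only up/down gene sets at one timepoint, with Venn provenance.

    Gene order within each direction is by |log2FC| descending then gene id, so
    truncation to a tag-set cap is deterministic. ``provenance`` records the
    AW DEG count and how many genes were excluded for overlapping the
    no-treatment or anesthesia-only DEG sets.
    """

    timepoint: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)

    def capped(self, cap: int) -> "WoundSignature":
        """Return a copy truncated to at most ``cap`` genes per direction."""
        return WoundSignature(
            timepoint=self.timepoint,
            up_genes=self.up_genes[:cap],
            down_genes=self.down_genes[:cap],
            provenance=dict(self.provenance, tag_cap=cap),
        )


@dataclass
class ReferenceSignatureSet:
    """A perturbagen signature database: z-scores plus two annotation layers.

    ``z`` is gene x signature (level-5-style differential z-scores); ``sig_meta``
    maps each signature id to its perturbagen (columns ``pert_id`` and free
    annotation columns); ``pert_meta`` maps perturbagen id to mechanism-of-action
    and clinical phase.
    """

    z: pd.DataFrame
    sig_meta: pd.DataFrame
    pert_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.z.columns.duplicated().any():
            raise ValueError("duplicate signature ids in reference matrix")
        missing = set(self.z.columns) - set(self.sig_meta.index)
        if missing:
            raise ValueError(f"signatures without metadata: {sorted(missing)[:5]}")

    def perturbagen_of(self, sig_id: str) -> str:
        return str(self.sig_meta.loc[sig_id, "pert_id"])


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset.

    ``gene_class`` maps timepoint -> gene id -> effect class (one of
    ``GENE_CLASSES``); genes absent from a timepoint's mapping are null there.
    """

    gene_class: dict[str, dict[str, str]] = field(default_factory=dict)
    reverser_compounds: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)

    def genes_of(self, timepoint: str, *classes: str) -> set[str]:
        mapping = self.gene_class.get(timepoint, {})
        return {g for g, c in mapping.items() if c in classes}

    def wound_genes(self, timepoint: str) -> set[str]:
        return self.genes_of(timepoint, "wound_up", "wound_down")


def check_design_labels(samples: pd.DataFrame) -> None:
    """Validate a sample-metadata table's timepoint/intervention labels."""
    bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS) - {BASELINE}
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    bad_iv = set(samples["intervention"]) - set(INTERVENTIONS) - {BASELINE}
    if bad_iv:
        raise ValueError(f"unknown interventions: {sorted(bad_iv)}")


def as_integer_counts(values: np.ndarray) -> np.ndarray:
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.rint(values)
        if not np.allclose(values, rounded):
            raise ValueError("count matrix contains non-integer values")
        values = rounded.astype(np.int64)
    return values
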