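"""Seeded synthetic data emulating the study design, with planted ground truth.

The generators stand in for the deposited tumor RNA-seq data and the LINCS
reference so that every pipeline stage can be exercised and its recovery
measured against known truth:

* ``simulate_counts`` — negative-binomial gene counts for the 10-subgroup
  design (baseline plus N/A/AW arms at three post-intervention timepoints),
  with three planted per-timepoint effect programs: *progression* genes shift
  in all three arms relative to baseline, *anesthesia* genes shift in the A and
  AW arms, and *wound* genes shift only in the AW arm (half up, half down).
  Only the wound program should survive the Venn exclusion downstream.
* ``simulate_reference`` — an L1000-like z-score matrix (many signatures per
  perturbagen) in which a chosen number of reverser compounds load negatively
  on the wound-up genes and positively on the wound-down genes.
* ``simulate_gmt`` — random gene-set collections with one planted set
  overlapping the wound signature.
* ``simulate_tumor_weights`` — per-group normal tumor-weight draws.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from woundsig.containers import (
    BASELINE,
    CountExperiment,
    GroundTruth,
    INTERVENTIONS,
    ReferenceSignatureSet,
    SUBGROUPS,
    TIMEPOINTS,
    WoundSignature,
)

#: Per-subgroup sample sizes of the emulated study (unequal by design).
STUDY_SUBGROUP_SIZES = {
    "Base": 5,
    "T1_N": 3,
    "T1_A": 2,
    "T1_AW": 4,
    "T2_N": 5,
    "T2_A": 9,
    "T2_AW": 6,
    "T3_N": 5,
    "T3_A": 6,
    "T3_AW": 3,
}

GENE_LENGTH_RANGE = (500, 10000)

_MOA_POOL = (
    "HDAC inhibitor",
    "protein synthesis inhibitor",
    "GSK3 inhibitor",
    "SMAC mimetic",
    "ER antagonist",
    "HMG-CoA reductase inhibitor",
    "tyrosine kinase inhibitor",
    "BCL-2 inhibitor",
    "DNA damage inducer",
    "IDH1 inhibitor",
)
_PHASE_POOL = ("Preclinical", "Phase 1", "Phase 2", "Phase 3", "Launched")


@dataclass
class SimDesign:
    """Configuration of the synthetic count experiment.

    ``n_progression``, ``n_anesthesia`` and ``n_wound`` are planted gene counts
    per timepoint; the three classes are disjoint within a timepoint but drawn
    independently across timepoints. ``effect_log2fc`` is applied
    multiplicatively to the negative-binomial mean so planted fold changes are
    exact on the mean scale. Baseline log means are normal with
    ``mean_log_loc``/``mean_log_scale`` (natural-log scale).
    """

    n_genes: int = 5000
    subgroup_sizes: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_SUBGROUP_SIZES)
    )
    n_progression: int = 150
    n_anesthesia: int = 100
    n_wound: int = 200
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_log_loc: float = 5.0
    mean_log_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for label, n in self.subgroup_sizes.items():
            if label not in SUBGROUPS:
                raise ValueError(f"unknown subgroup label {label!r}")
            if n < 0:
                raise ValueError(f"subgroup {label}: negative size")
        planted = self.n_progression + self.n_anesthesia + self.n_wound
        if planted > self.n_genes:
            raise ValueError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )
        if min(self.n_progression, self.n_anesthesia, self.n_wound) < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        has_effects = planted > 0 and self.effect_log2fc > 0
        for tp in TIMEPOINTS:
            for iv in INTERVENTIONS:
                label = f"{tp}_{iv}"
                if has_effects and self.subgroup_sizes.get(label, 0) == 0:
                    raise ValueError(
                        f"subgroup {label} has size 0 but its timepoint carries planted effects"
                    )


def simulate_counts(design: SimDesign) -> tuple[CountExperiment, GroundTruth]:
    """Generate the 10-subgroup count experiment with planted effect classes."""
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    lengths = pd.Series(
        rng.integers(GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1, design.n_genes),
        index=genes,
        name="gene_length",
    )
    base_mean = np.exp(
        rng.normal(design.mean_log_loc, design.mean_log_scale, design.n_genes)
    )

    truth = GroundTruth()
    up_mult = 2.0**design.effect_log2fc
    down_mult = 2.0**-design.effect_log2fc
    # per-timepoint multiplier per intervention arm, default 1
    multipliers: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        n_planted = design.n_progression + design.n_anesthesia + design.n_wound
        chosen = rng.choice(design.n_genes, size=n_planted, replace=False)
        prog = chosen[: design.n_progression]
        anes = chosen[design.n_progression : design.n_progression + design.n_anesthesia]
        wound = chosen[design.n_progression + design.n_anesthesia :]
        wound_up = wound[: len(wound) // 2 + len(wound) % 2]
        wound_down = wound[len(wound) // 2 + len(wound) % 2 :]

        classes: dict[str, str] = {}
        for arr, label in ((prog, "progression"), (anes, "anesthesia")):
            for k, idx in enumerate(arr):
                classes[genes[idx]] = label
        for idx in wound_up:
            classes[genes[idx]] = "wound_up"
        for idx in wound_down:
            classes[genes[idx]] = "wound_down"
        truth.gene_class[tp] = classes

        for iv in INTERVENTIONS:
            mult = np.ones(design.n_genes)
            # progression affects every arm; alternate directions for realism
            for k, idx in enumerate(prog):
                mult[idx] *= up_mult if k % 2 == 0 else down_mult
            if iv in ("A", "AW"):
                for k, idx in enumerate(anes):
                    mult[idx] *= up_mult if k % 2 == 0 else down_mult
            if iv == "AW":
                mult[wound_up] *= up_mult
                mult[wound_down] *= down_mult
            multipliers[f"{tp}_{iv}"] = mult

    sample_ids, tp_labels, iv_labels, columns = [], [], [], []
    r_param = 1.0 / design.nb_dispersion
    for label in SUBGROUPS:
        n = design.subgroup_sizes.get(label, 0)
        if label == BASELINE:
            mult, tp, iv = np.ones(design.n_genes), BASELINE, BASELINE
        else:
            mult = multipliers[label]
            tp, iv = label.split("_")
        means = base_mean * mult
        p_nb = r_param / (r_param + means)
        for rep in range(1, n + 1):
            sample_ids.append(f"{label}_{rep}")
            tp_labels.append(tp)
            iv_labels.append(iv)
            columns.append(rng.negative_binomial(r_param, p_nb))

    counts = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=sample_ids
    )
    samples = pd.DataFrame(
        {"timepoint": tp_labels, "intervention": iv_labels},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountExperiment(counts=counts, gene_lengths=lengths, samples=samples), truth


def true_wound_signature(truth: GroundTruth, timepoint: str) -> WoundSignature:
    """The planted wound signature at a timepoint (for recovery tests)."""
    classes = truth.gene_class[timepoint]
    return WoundSignature(
        timepoint=timepoint,
        up_genes=sorted(g for g, c in classes.items() if c == "wound_up"),
        down_genes=sorted(g for g, c in classes.items() if c == "wound_down"),
    )


def random_wound_signature(
    universe: list[str], n_up: int, n_down: int, seed: int
) -> WoundSignature:
    """A random up/down signature drawn from a gene universe (test helper)."""
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(universe), size=n_up + n_down, replace=False)
    return WoundSignature(
        timepoint="T1",
        up_genes=[universe[i] for i in picked[:n_up]],
        down_genes=[universe[i] for i in picked[n_up:]],
    )


def simulate_reference(
    n_genes: int,
    n_compounds: int,
    sigs_per_compound: int,
    n_reversers: int,
    wound_signature: WoundSignature,
    seed: int,
    loading: float = 2.0,
    noise_sd: float = 1.0,
    universe: list[str] | None = None,
) -> tuple[ReferenceSignatureSet, GroundTruth]:
    """Generate an L1000-like z-score reference with planted reverser compounds.

    The gene universe contains every wound-signature gene plus filler genes up
    to ``n_genes`` — drawn from ``universe`` when given (so unrelated queries
    can still match measured genes), otherwise synthetic ids. Non-reverser
    signatures are i.i.d. standard normal; reverser signatures add
    ``-loading`` on the wound-up genes and ``+loading`` on the wound-down
    genes to the noise.
    """
    sig_genes = list(wound_signature.up_genes) + list(wound_signature.down_genes)
    if not sig_genes:
        raise ValueError("wound signature is empty")
    if len(sig_genes) > n_genes:
        raise ValueError("wound signature larger than the reference gene universe")
    if n_reversers > n_compounds:
        raise ValueError("n_reversers exceeds n_compounds")
    rng = np.random.default_rng(seed)
    n_filler = n_genes - len(sig_genes)
    if universe is not None:
        pool = sorted(set(universe) - set(sig_genes))
        if len(pool) < n_filler:
            raise ValueError("universe too small to fill the reference gene panel")
        filler = [pool[i] for i in rng.choice(len(pool), n_filler, replace=False)]
    else:
        filler = [f"R{i:05d}" for i in range(n_filler)]
    genes = sig_genes + filler

    pert_ids = [f"CMPD-{i:04d}" for i in range(1, n_compounds + 1)]
    reversers = set(
        np.asarray(pert_ids)[
            rng.choice(n_compounds, size=n_reversers, replace=False)
        ].tolist()
    )
    n_sigs = n_compounds * sigs_per_compound
    z = rng.normal(0.0, noise_sd, size=(n_genes, n_sigs))

    up_idx = np.arange(len(wound_signature.up_genes))
    down_idx = np.arange(len(wound_signature.up_genes), len(sig_genes))
    sig_ids, sig_pert = [], []
    col = 0
    for pert in pert_ids:
        for _ in range(sigs_per_compound):
            sig_ids.append(f"SIG-{col + 1:05d}")
            sig_pert.append(pert)
            if pert in reversers:
                z[up_idx, col] -= loading
                z[down_idx, col] += loading
            col += 1

    zdf = pd.DataFrame(z, index=genes, columns=sig_ids)
    sig_meta = pd.DataFrame(
        {
            "pert_id": sig_pert,
            "dose_um": np.round(rng.choice([0.1, 1.0, 10.0], size=n_sigs), 3),
            "cell_line": rng.choice(["A375", "MCF7", "PC3", "HT29"], size=n_sigs),
        },
        index=pd.Index(sig_ids, name="signature_id"),
    )
    pert_meta = pd.DataFrame(
        {
            "moa": [_MOA_POOL[i % len(_MOA_POOL)] for i in range(n_compounds)],
            "phase": [_PHASE_POOL[i % len(_PHASE_POOL)] for i in range(n_compounds)],
        },
        index=pd.Index(pert_ids, name="pert_id"),
    )
    reference = ReferenceSignatureSet(z=zdf, sig_meta=sig_meta, pert_meta=pert_meta)
    return reference, GroundTruth(reverser_compounds=reversers)


def simulate_gmt(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_signature: WoundSignature | list[str],
    seed: int,
    planted_overlap_fraction: float = 0.6,
) -> tuple[dict[str, list[str]], GroundTruth]:
    """Random gene sets plus one planted set overlapping the wound signature."""
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed the universe size")
    rng = np.random.default_rng(seed)
    sig_genes = (
        sorted(planted_signature.genes)
        if isinstance(planted_signature, WoundSignature)
        else sorted(planted_signature)
    )
    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = sorted(universe[j] for j in idx)

    size = int(rng.integers(lo, hi + 1))
    n_from_sig = min(int(round(planted_overlap_fraction * size)), len(sig_genes))
    from_sig = list(
        np.asarray(sig_genes)[rng.choice(len(sig_genes), n_from_sig, replace=False)]
    )
    others = sorted(set(universe) - set(from_sig))
    n_filler = size - n_from_sig
    filler = list(np.asarray(others)[rng.choice(len(others), n_filler, replace=False)])
    sets["PLANTED_WOUND_SET"] = sorted(from_sig + filler)
    return sets, GroundTruth(enriched_terms={"PLANTED_WOUND_SET"})


#: Group mean/sd defaults (grams) emulating the study's tumor-burden pattern:
#: wounding raises burden clearly at the first timepoint, later timepoints show
#: the same trend with larger spread.
TUMOR_WEIGHT_DESIGN = {
    "T1": {"N": (1.0, 0.3), "A": (1.1, 0.3), "AW": (1.6, 0.3)},
    "T2": {"N": (1.4, 0.5), "A": (1.5, 0.5), "AW": (1.8, 0.5)},
    "T3": {"N": (1.8, 0.6), "A": (1.9, 0.6), "AW": (2.2, 0.6)},
}


def simulate_tumor_weights(
    group_means: dict | None = None,
    group_sds: dict | None = None,
    group_ns: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Normal tumor-weight draws per timepoint x intervention group.

    ``group_means``/``group_sds`` map ``(timepoint, intervention)`` labels like
    ``"T1_AW"`` to values; ``group_ns`` to sample counts (default 10, matching
    the per-arm allocation). Negative draws are clipped at zero.
    """
    means, sds = {}, {}
    for tp, arms in TUMOR_WEIGHT_DESIGN.items():
        for iv, (m, s) in arms.items():
            means[f"{tp}_{iv}"] = m
            sds[f"{tp}_{iv}"] = s
    if group_means:
        means.update(group_means)
    if group_sds:
        sds.update(group_sds)
    ns = {label: 10 for label in means}
    if group_ns:
        ns.update(group_ns)
    for label, n in ns.items():
        if n < 2:
            raise ValueError(f"group {label}: need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(means):
        tp, iv = label.split("_")
        draws = np.clip(rng.normal(means[label], sds[label], ns[label]), 0.0, None)
        for k, w in enumerate(draws, start=1):
            rows.append(
                {
                    "mouse_id": f"{label}_{k}",
                    "timepoint": tp,
                    "intervention": iv,
                    "weight": float(w),
                }
            )
    return pd.DataFrame(rows)
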