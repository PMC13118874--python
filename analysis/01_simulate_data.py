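"""Generate the synthetic study: counts, tumor weights, gene sets.

Emulates the three-arm (N / A / AW), four-timepoint design with its unequal
subgroup sizes, planting per-timepoint progression, anesthesia and wound
programs at |log2FC| = 2 into negative-binomial counts. Ground-truth labels
are written alongside so later scripts can measure recovery.
"""

import pandas as pd

from common import DATA_DIR, N_GENES, RESULTS_DIR, SEED, ensure_dirs
from woundsig import io as wio
from woundsig import synthetic_data as syn


def main() -> None:
    ensure_dirs()
    design = syn.SimDesign(n_genes=N_GENES, seed=SEED)
    experiment, truth = syn.simulate_counts(design)
    wio.write_counts(experiment, DATA_DIR / "counts.tsv")
    wio.write_sample_metadata(experiment.samples, DATA_DIR / "sample_metadata.tsv")

    truth_rows = [
        {"timepoint": tp, "gene_id": g, "gene_class": c}
        for tp, classes in truth.gene_class.items()
        for g, c in sorted(classes.items())
    ]
    pd.DataFrame(truth_rows).to_csv(DATA_DIR / "ground_truth_genes.tsv", sep="\t", index=False)

    weights = syn.simulate_tumor_weights(seed=SEED + 1)
    weights.to_csv(DATA_DIR / "tumor_weights.tsv", sep="\t", index=False)

    summary = (
        experiment.samples.groupby(["timepoint", "intervention"]).size().rename("n_samples")
    )
    summary.to_csv(RESULTS_DIR / "design_summary.tsv", sep="\t")
    print(f"simulated {experiment.counts.shape[0]} genes x {experiment.counts.shape[1]} samples")
    print(summary.to_string())
    print(f"planted per timepoint: {design.n_progression} progression, "
          f"{design.n_anesthesia} anesthesia, {design.n_wound} wound genes at |log2FC|={design.effect_log2fc}")


if __name__ == "__main__":
    main()
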