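"""Over-representation analysis of each wound signature with kappa clustering.

A synthetic gene-set collection (30 random sets plus one planted set built to
overlap the T1 wound signature) stands in for curated pathway databases. The
planted set should pass the count > 3 / p < 0.01 filters; random sets should
not, beyond chance.
"""

import pandas as pd

from common import DATA_DIR, RESULTS_DIR, SEED, ensure_dirs
from woundsig import io as wio
from woundsig import synthetic_data as syn
from woundsig.containers import TIMEPOINTS
from woundsig.enrichment import run_ora


def main() -> None:
    ensure_dirs()
    counts = pd.read_csv(DATA_DIR / "counts.tsv", sep="\t", index_col=0)
    universe = [g for g in counts.index]
    t1_sig = wio.read_signature_gmt(DATA_DIR / "wsdeg_T1.gmt", "T1")
    collections, truth = syn.simulate_gmt(universe, 30, (30, 100), t1_sig, seed=SEED + 2)
    wio.write_gmt(collections, DATA_DIR / "gene_sets.gmt")
    planted = next(iter(truth.enriched_terms))

    for tp in TIMEPOINTS:
        ws = wio.read_signature_gmt(DATA_DIR / f"wsdeg_{tp}.gmt", tp)
        result = run_ora(ws.genes, collections, set(universe))
        result.table.to_csv(RESULTS_DIR / f"enrichment_{tp}.tsv", sep="\t")
        hits = result.table[result.table["passed"]]
        print(f"{tp}: {len(hits)} significant terms "
              f"({'planted set detected' if planted in hits.index else 'planted set NOT detected'})")
        if not hits.empty:
            print(hits[["overlap_count", "set_size", "p_hyper", "q_bh", "cluster_id"]]
                  .to_string(float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
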