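"""Compare tumor weights between intervention arms at each timepoint.

Pooled-variance Student t-tests for AW vs N, AW vs A and A vs N. Under the
default generator settings the wounding effect is clearest at the first
postoperative timepoint, mirroring an early surge in tumor burden after
surgical injury.
"""

import pandas as pd

from common import DATA_DIR, RESULTS_DIR, ensure_dirs
from woundsig.differential_expression import compare_tumor_burden


def main() -> None:
    ensure_dirs()
    weights = pd.read_csv(DATA_DIR / "tumor_weights.tsv", sep="\t")
    table = compare_tumor_burden(weights)
    table.to_csv(RESULTS_DIR / "tumor_burden.tsv", sep="\t", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    t1 = table[(table["timepoint"] == "T1") & (table["group_b"] == "N")
               & (table["group_a"] == "AW")].iloc[0]
    verdict = "significant" if t1["p"] < 0.05 else "not significant"
    print(f"\nT1 AW vs N: p = {t1['p']:.4g} ({verdict})")


if __name__ == "__main__":
    main()
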