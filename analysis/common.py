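"""Shared paths and the study-scale settings used by the analysis scripts.

Scripts are run from the repository root in numeric order. Bulky intermediate
matrices live under ``scratch/`` (regenerable, not part of the deliverable
tables); compact summary tables go to ``results/``.
"""

from pathlib import Path

DATA_DIR = Path("scratch/analysis_data")
RESULTS_DIR = Path("results")

SEED = 20260921  # analysis-wide base seed
N_GENES = 5000

REFERENCE_SHAPE = dict(n_genes=978, n_compounds=200, sigs_per_compound=10, n_reversers=5)
TOP_K = 100  # scaled to the 2000-signature synthetic reference


def ensure_dirs() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
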