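"""Shared fixtures: small seeded synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from woundsig import normalization
from woundsig import synthetic_data as syn
from woundsig import differential_expression as de


@pytest.fixture(scope="session")
def small_design():
    return syn.SimDesign(
        n_genes=1200,
        n_progression=60,
        n_anesthesia=60,
        n_wound=120,
        effect_log2fc=2.0,
        nb_dispersion=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design):
    experiment, truth = syn.simulate_counts(small_design)
    return experiment, truth


@pytest.fixture(scope="session")
def small_expression(small_experiment):
    experiment, _ = small_experiment
    return normalization.normalize(experiment)


@pytest.fixture(scope="session")
def t1_deg_tables(small_expression):
    return {
        iv: de.test_contrast(small_expression, de.ContrastSpec("T1", iv))
        for iv in ("N", "A", "AW")
    }


def make_deg_table(calls: dict, timepoint="T1", intervention="AW") -> de.DegTable:
    """Build a DegTable from {gene: log2fc} where every listed gene is a DEG."""
    genes = sorted(calls)
    table = pd.DataFrame(
        {
            "log2fc": [calls[g] for g in genes],
            "p_raw": 0.001,
            "q_storey": 0.5,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    deg = de.DegTable(table=table, timepoint=timepoint, intervention=intervention)
    return de.call_degs(deg)


@pytest.fixture
def deg_factory():
    return make_deg_table
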