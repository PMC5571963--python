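import numpy as np
import pandas as pd
import pytest

import fracrna as fr


@pytest.fixture
def small_design():
    return fr.SimDesign(n_mpr=10, n_cpr=30, n_other=6,
                        fractions=("extract", "membrane", "70S"),
                        n_replicates=2, library_size=3e5,
                        dispersion=0.02, seed=11)


@pytest.fixture
def small_catalog(small_design):
    return fr.build_gene_catalog(small_design)


@pytest.fixture
def small_counts(small_design, small_catalog):
    truth = fr.make_truth(small_catalog, small_design,
                          class_effects={"membrane": {"MPR": 3.0}})
    return fr.simulate_fraction_counts(small_catalog, small_design, truth), truth


@pytest.fixture
def toy_catalog():
    """Hand-built 5-gene catalog: 3 mRNA (2 MPR, 1 CPR), 2 rRNA."""
    return pd.DataFrame(
        {
            "cds_length": [1000, 500, 2000, 1500, 3000],
            "loc_class": ["MPR", "MPR", "CPR", "other", "other"],
            "feature_class": ["mRNA", "mRNA", "mRNA", "rRNA", "rRNA"],
        },
        index=pd.Index(["g1", "g2", "g3", "r1", "r2"], name="gene_id"),
    )


@pytest.fixture
def toy_counts(toy_catalog):
    counts = pd.DataFrame(
        {
            "extract_rep1": [100, 50, 400, 3000, 5000],
            "membrane_rep1": [300, 150, 200, 4000, 6000],
        },
        index=toy_catalog.index,
    )
    samples = pd.DataFrame(
        {"fraction": ["extract", "membrane"], "replicate": [1, 1]},
        index=pd.Index(["extract_rep1", "membrane_rep1"], name="sample_id"),
    )
    return fr.CountMatrix(counts, samples)
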