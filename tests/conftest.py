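import numpy as np
import pandas as pd
import pytest

from isomed.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One medium cohort with the planted Iso2 -> TNF -> T-cell-module chain."""
    spec = CohortSpec(n_samples=300, n_decoy_genes=20, n_pathways=5, seed=42)
    expr, annot, truth = generate_cohort(spec)
    return spec, expr, annot, truth


@pytest.fixture()
def treatment(small_cohort):
    _, _, annot, _ = small_cohort
    return (annot["iso2"] > 0).to_numpy().astype(float)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
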