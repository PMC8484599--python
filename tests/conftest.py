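"""Shared fixtures: one mid-sized synthetic study reused across modules."""

import numpy as np
import pandas as pd
import pytest

from microbopred.otu_processing import OTUTable
from microbopred.pipeline import process_counts
from microbopred.synthetic_data import SimulationConfig, simulate_study
from microbopred.traits import derive_phenotypes


@pytest.fixture(scope="session")
def study():
    """~450-animal study with all variance sources active."""
    cfg = SimulationConfig(
        n_founders=30, n_generations=2, n_otus=120, mean_depth=4000,
        frac_regime_restricted=0.3, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def css_table(study):
    return process_counts(study.otu_counts)


@pytest.fixture(scope="session")
def phenotypes(study):
    return derive_phenotypes(study.design, study.bw_records, study.cage_fi)


@pytest.fixture()
def toy_counts():
    """4 samples x 5 OTUs with hand-checkable structure."""
    df = pd.DataFrame(
        [[10, 0, 5, 1, 0],
         [20, 0, 10, 2, 0],
         [0, 8, 0, 0, 3],
         [5, 5, 5, 5, 5]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"O{j}" for j in range(1, 6)])
    return OTUTable(df, stage="raw_counts")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
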