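import numpy as np
import pytest

from microcross.harness import prepare_dataset
from microcross.models import ClassifierSpec
from microcross.simulate import SimConfig, simulate_multicohort


@pytest.fixture(scope="session")
def tiny_sim():
    """Small 3-cohort dataset with consistent markers and its ground truth."""
    cfg = SimConfig(
        n_cohorts=3, n_case=24, n_control=24, n_taxa=80, n_markers=15, seed=3
    )
    return simulate_multicohort(cfg)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim):
    return tiny_sim[0]


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    """(modeling dataset, lefse tables) after QC + batch adjustment."""
    return prepare_dataset(tiny_dataset)


@pytest.fixture()
def light_spec():
    """Single-repeat classifier spec with a short grid for fast unit tests."""
    return ClassifierSpec(
        repeats=1, c_grid=tuple(np.logspace(-2, 2, 8)), seed=7
    )
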