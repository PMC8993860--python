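import numpy as np
import pytest

from valuelearn.design import (
    DEFAULT_CUE_IDS,
    DesignConfig,
    ReinforcerKind,
    assign_pairings,
    build_latin_square,
    make_conditioning_schedule,
)
from valuelearn.cohort import sample_cohort


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def pairing(config):
    square = build_latin_square(config.n_conditions)
    return assign_pairings(0, square, DEFAULT_CUE_IDS, tuple(ReinforcerKind))


@pytest.fixture(scope="session")
def schedule(config, pairing):
    return make_conditioning_schedule(config, pairing, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-participant cohort shared across read/write and analysis tests."""
    return sample_cohort(n=6, seed=42)


@pytest.fixture(scope="session")
def midsize_cohort():
    """A full-size (n=72) cohort without beat series, for inference tests."""
    return sample_cohort(n=72, seed=7, simulate_beats=False)
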