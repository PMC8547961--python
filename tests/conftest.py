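import numpy as np
import pytest

from oncospectra import (SimConfig, WavenumberGrid, default_disease_signature,
                         default_serum_bands, generate_cohort,
                         water_reference_spectrum)


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def water(grid):
    return water_reference_spectrum(grid)


@pytest.fixture(scope="session")
def bands():
    return default_serum_bands()


@pytest.fixture(scope="session")
def signature(grid):
    return default_disease_signature(grid)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest case/reference cohort with signal, confounding and shifts."""
    cfg = SimConfig(n_cases=40, n_refs=50, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
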