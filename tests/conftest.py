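import numpy as np
import pytest

from gliaflow.panels import panel_markers
from gliaflow.synthetic import (
    default_cohort,
    default_effects,
    default_populations,
    generate_sample,
)


@pytest.fixture(scope="session")
def m1_populations():
    return default_populations("M1")


@pytest.fixture(scope="session")
def m1_effects():
    return default_effects("M1")


@pytest.fixture(scope="session")
def sham_sample(m1_populations, m1_effects):
    """One sham M1 sample: 10,000 cell events + 1,000 beads, fixed seed."""
    return generate_sample(m1_populations, m1_effects[("sham", "ipsilateral")],
                           10_000, seed=42)


@pytest.fixture(scope="session")
def cci_sample(m1_populations, m1_effects):
    return generate_sample(m1_populations, m1_effects[("CCI", "ipsilateral")],
                           10_000, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-effect cohort at reduced size for fast smoke tests."""
    return default_cohort(seed=123, n_events=2000)


@pytest.fixture(scope="session")
def m1_markers():
    return list(panel_markers("M1"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
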