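import numpy as np
import pytest

from phageome.discovery import run_discovery
from phageome.synthetic_community import generate_cohort, generate_community


@pytest.fixture(scope="session")
def default_community():
    """The default study community: 30 phages / 20 plasmids / 30 bacterial
    contigs at 2% annotation flip-noise, seed 42."""
    return generate_community(seed=42, noise=0.02)


@pytest.fixture(scope="session")
def noisefree_community():
    return generate_community(seed=42, noise=0.0)


@pytest.fixture(scope="session")
def default_discovery(default_community):
    calls, reports = run_discovery(default_community.contigs)
    return calls, reports


@pytest.fixture(scope="session")
def noisefree_discovery(noisefree_community):
    calls, reports = run_discovery(noisefree_community.contigs)
    return calls, reports


@pytest.fixture(scope="session")
def cohort500():
    return generate_cohort(n_samples=500, rng_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
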