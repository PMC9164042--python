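import pytest
from hypothesis import settings

from nsafpipe import SimulationParams, StudyDesign, simulate_study

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return StudyDesign.chorionic_villus_study()


@pytest.fixture(scope="session")
def default_study(design):
    """A moderately sized synthetic study under the default generator
    conditions (mixed stable/unstable, contaminants on both sides of the
    exclusion boundary, dataset-specific proteins)."""
    return simulate_study(design, SimulationParams(n_proteins=400, seed=5))


@pytest.fixture(scope="session")
def separated_study(design):
    """A study with well-separated abundance classes and a near-noiseless
    stable replicate factor, for ground-truth recovery checks."""
    return simulate_study(design, SimulationParams.well_separated(n_proteins=600, seed=11))
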