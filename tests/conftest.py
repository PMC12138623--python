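import pytest

from gutmetab.simulate import SimulationDesign, simulate_study
from gutmetab.taxonomy import assign_all


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (seed 0), shared read-only across tests."""
    return simulate_study(SimulationDesign(seed=0))


@pytest.fixture(scope="session")
def assignments(study):
    """MTA assignments for the default study's ASVs (alignment is the slow part)."""
    return assign_all(study.asv_sequences, study.reference)
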