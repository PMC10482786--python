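import pytest

from glocal.design import build_session
from glocal.synth import PopulationConfig, sample_population, simulate_study


@pytest.fixture(scope="session")
def numeric_design():
    return build_session("numeric", seed=0)


@pytest.fixture(scope="session")
def preference_design():
    return build_session("preference", seed=0)


@pytest.fixture(scope="session")
def study30():
    """One 30-subject synthetic study at generating rho_theta = 0.8.

    Shared across recovery and index tests; (numeric, preference, truth).
    """
    cfg = PopulationConfig(n_subjects=30, rho_theta=0.8, seed=11)
    return simulate_study(sample_population(cfg), seed=22)
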