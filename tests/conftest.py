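import pytest

from agroportfolio import (
    load_baseline_coefficients,
    make_default_fixture,
    simulate_indicators,
)


@pytest.fixture(scope="session")
def study_fixture():
    """The packaged synthetic seven-land-use study system."""
    return make_default_fixture(1)


@pytest.fixture(scope="session")
def baseline_table():
    """The published baseline coefficient table (7 land uses x 5 indicators)."""
    return load_baseline_coefficients()


@pytest.fixture(scope="session")
def mc_result(study_fixture):
    """One shared full-depth Monte-Carlo run on the default fixture."""
    return simulate_indicators(study_fixture, n_reps=10_000, seed=123)
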