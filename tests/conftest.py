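import pytest

from cathquant import fixtures
from cathquant.synthetic_data import default_params


@pytest.fixture(scope="session")
def method():
    return fixtures.load_method()


@pytest.fixture(scope="session")
def screen_method():
    return fixtures.load_screen_method()


@pytest.fixture(scope="session")
def params(method, screen_method):
    return default_params(method, screen=screen_method, seed=123)


@pytest.fixture(scope="session")
def clean_params(method, screen_method):
    """Noise-free simulation parameters for closed-form checks."""
    return default_params(
        method,
        screen=screen_method,
        seed=123,
        baseline_noise_sd=0.0,
        within_run_cv=0.0,
        between_run_cv=0.0,
    )
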