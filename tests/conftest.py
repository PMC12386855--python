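import warnings

import pytest

from sitdemog.bayes_binomial import ConvergenceWarning
from sitdemog.synthetic_data import GeneratorParams, canonical_design, simulate_trial


@pytest.fixture(scope="session")
def design():
    return canonical_design()


@pytest.fixture(scope="session")
def trial(design):
    """One canonical synthetic trial (cohorts, intervals, water)."""
    return simulate_trial(design, GeneratorParams(seed=1))


@pytest.fixture()
def ignore_convergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield
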