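import warnings

import pytest

from trialcea.synthetic_trial import (
    TrialConfig,
    apply_missingness,
    generate_trial,
    make_fixtures,
)

# statsmodels emits boundary/convergence chatter on permuted or degenerate
# fits; the suites assert on the results, not the chatter.
warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture(scope="session")
def tables():
    """(UnitCostTable, ValueSet, CPISeries) synthetic fixtures."""
    return make_fixtures()


@pytest.fixture(scope="session")
def small_config():
    return TrialConfig(n_per_arm=60, n_centres=3, n_practices=12, seed=11)


@pytest.fixture(scope="session")
def small_trial(small_config):
    """Complete (no missingness) small synthetic trial."""
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def small_trial_missing(small_config, small_trial):
    return apply_missingness(small_trial, small_config)


@pytest.fixture(scope="session")
def default_trial():
    """Full-size trial at the published design (3 x 329)."""
    return generate_trial(TrialConfig(seed=20))
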