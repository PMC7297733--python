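import pytest

from mthijack.reference import builtin_profiles
from mthijack.synthetic_cohort import SimulationConfig, simulate_ctvt_cohort

SUITE_SEED = 101


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 539 tumours, 19 events, 11 A1d1a."""
    return simulate_ctvt_cohort(SimulationConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def truth_labels(default_cohort):
    t = default_cohort.truth.tumours
    return dict(zip(t["tumour"], t["donor"]))
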