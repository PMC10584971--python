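import numpy as np
import pytest

from ivfsim import (
    ParameterRange,
    Strategy,
    reference_parameters,
    run_cohort,
    set_parameter,
)
from ivfsim.parameters import map_ranges

# cohort size and seed used by the full-scale reproduction tests
FULL_N = 100_000
FULL_SEED = 42


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231018)


def forced_success_params():
    """All probabilities 1, ICSI share 0, all costs fixed at midpoints.

    Forces the single certain path: fresh IVF cycle ending pregnant, with a
    hand-summable cost (1400 + 200 + 145 + 130 + 1000 + 30 + 450 + 150 = 3505
    for the myo-inositol arm).
    """
    params = map_ranges(
        reference_parameters(),
        lambda path, r: (
            ParameterRange.fixed(r.midpoint)
            if path.startswith("cost.")
            else ParameterRange.fixed(1.0)
        ),
    )
    return set_parameter(params, "fresh.icsi_share", ParameterRange.fixed(0.0))


@pytest.fixture()
def forced_success():
    return forced_success_params()


@pytest.fixture(scope="session")
def full_cohorts(ref_params):
    """One 100,000-patient cohort per arm on the reference tables."""
    return {
        s: run_cohort(ref_params, s, n=FULL_N, seed=FULL_SEED)
        for s in (Strategy.RFSH_MYOINS, Strategy.RFSH)
    }
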