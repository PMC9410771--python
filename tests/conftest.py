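import numpy as np
import pytest

from pulsespread import KineticParameters, PulseSpreadGeometry


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def fast_params() -> KineticParameters:
    """Quickly mixing rates for Monte-Carlo oracles (short sojourns, cheap)."""
    return KineticParameters(
        v_a=0.5,
        v_r=0.4,
        rate_run_to_pause_on=0.2,
        rate_pause_on_to_run=0.1,
        rate_on_to_off=0.05,
        rate_off_to_on=0.08,
        rate_reverse_a_to_r=0.03,
        rate_reverse_r_to_a=0.05,
    )


@pytest.fixture(scope="session")
def geometry() -> PulseSpreadGeometry:
    return PulseSpreadGeometry()


@pytest.fixture(scope="session")
def wide_geometry() -> PulseSpreadGeometry:
    """Flanks wide enough for complete capture over a 4-min interval."""
    return PulseSpreadGeometry(flank_lengths=(15.0, 60.0), domain_margin=200.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
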