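import numpy as np
import pytest

from fretkit import MaturationScenario, area_normalize, gen_spectrum


@pytest.fixture(scope="session")
def donor_emission():
    """mNeonGreen-like emission spectrum (peak 517 nm, right-skewed)."""
    return gen_spectrum(517, 15, skew=3)


@pytest.fixture(scope="session")
def acceptor_emission():
    """mScarlet-I-like emission spectrum (peak 593 nm, right-skewed)."""
    return gen_spectrum(593, 18, skew=3)


@pytest.fixture(scope="session")
def acceptor_absorption():
    """mScarlet-I-like absorption spectrum (peak 569 nm, left-skewed)."""
    return gen_spectrum(569, 20, skew=-3, kind="absorption_extinction")


@pytest.fixture(scope="session")
def donor_ref(donor_emission):
    return area_normalize(donor_emission)


@pytest.fixture(scope="session")
def acceptor_ref(acceptor_emission):
    return area_normalize(acceptor_emission)


@pytest.fixture(scope="session")
def ruby_scenario():
    """NG-mRuby3-like tandem: slow maturation, mature efficiency 27%."""
    return MaturationScenario(t_half_min=136.5, E_true=0.27, tau_D_ns=3.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
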