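import numpy as np
import pytest

from nsefold.polymer_dynamics import ZimmModelSpec
from nsefold.synthetic_data import FixtureRegistry


@pytest.fixture(scope="session")
def fixtures():
    return FixtureRegistry()


@pytest.fixture(scope="session")
def pd2_spec():
    """Acid-unfolded-like chain: ν=0.55, l=13.6 Å, η=1.7 mPa·s."""
    return ZimmModelSpec.from_chain(nu=0.55, l=13.6, eta=1.7,
                                    com_diffusion=3.0,
                                    internal_friction=50.89)


@pytest.fixture(scope="session")
def gaussian_spec():
    """Gaussian chain (ν=0.5) without internal friction."""
    return ZimmModelSpec.from_chain(nu=0.5, l=14.0, eta=1.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
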