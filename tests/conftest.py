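import numpy as np
import pytest

from myokin import reference as ref


@pytest.fixture(scope="session")
def control_rates():
    """Control-condition cycle constants, K_M(actin)-calibrated once per session."""
    return ref.control_rates()


@pytest.fixture(scope="session")
def emd_rates():
    """25 µM compound condition cycle constants."""
    return ref.emd_rates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
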