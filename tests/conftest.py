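import numpy as np
import pytest

from fretscape import AcquisitionConfig, DuplexSpec, build_duplex

#: printed three-state landscape of the mismatched donor-acceptor sample:
#: (lifetime ns, fractional amplitude)
THREE_STATE = [(0.40, 0.39), (1.7, 0.33), (5.2, 0.28)]
DONOR_ONLY = [(4.9, 1.0)]
TAU_D = 4.9


@pytest.fixture(scope="session")
def default_acq():
    return AcquisitionConfig(seed=11)


@pytest.fixture(scope="session")
def small_acq():
    """Reduced channel count for fast unit tests."""
    return AcquisitionConfig(window=50.0, n_channels=512, peak_counts=5000.0,
                             seed=11)


@pytest.fixture(scope="session")
def straight_duplex():
    return build_duplex(DuplexSpec("ACGTACGTACGTACGTACGTACGT"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
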