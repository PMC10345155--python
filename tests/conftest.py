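import numpy as np
import pytest

from gpx4kin import KineticParameters, ReactionConditions

# Two parameter regimes of the interfacial model.  Slow docking relative
# to the surface cycle delays the build-up of bound enzyme (rate rises
# to an interior maximum); fast docking equilibrates within seconds and
# the rate is substrate-limited from the start.
SLOW_BINDING = KineticParameters(k_A=40.0, k_B=3e-3, k_1s=1e4, k_2s=1e5)
FAST_BINDING = KineticParameters(k_A=1e3, k_B=0.1, k_1s=1e6, k_2s=1e7)


@pytest.fixture(scope="session")
def slow_binding_params() -> KineticParameters:
    return SLOW_BINDING


@pytest.fixture(scope="session")
def fast_binding_params() -> KineticParameters:
    return FAST_BINDING


@pytest.fixture(scope="session")
def liposome_conditions() -> ReactionConditions:
    """Standard liposome assay: 0.4 mM phospholipid, 50 µM SLPCOOH."""
    return ReactionConditions(E_total=9.5e-9, M_total=4e-4, ROOH_0=5e-5)


@pytest.fixture(scope="session")
def time_grid() -> np.ndarray:
    return np.arange(0.0, 901.0, 1.0)
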