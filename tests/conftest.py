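import numpy as np
import pytest

from biodegkin import (
    DoubleExpDelayParams,
    SyntheticSpec,
    generate_synthetic,
    load_fixture,
)


@pytest.fixture(scope="session")
def wastewater():
    return load_fixture("bioreactor_wastewater")


@pytest.fixture(scope="session")
def bega():
    return load_fixture("bioreactor_bega")


@pytest.fixture(scope="session")
def tropical():
    return load_fixture("gordon_tropical")


@pytest.fixture(scope="session")
def two_phase_truth():
    """A well-conditioned two-phase parameter set used across recovery tests."""
    return DoubleExpDelayParams(w1_inf=40.0, T1=2.0, tau=10.0, w2_inf=40.0,
                                T2=3.0)


@pytest.fixture(scope="session")
def dense_two_phase_series(two_phase_truth):
    """Noiseless half-day sampling of the two-phase truth over 30 days."""
    return generate_synthetic(
        SyntheticSpec("double_exp_delay", two_phase_truth,
                      np.arange(0.0, 30.01, 0.5))
    )
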