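import numpy as np
import pytest

from otosat import (
    DEFAULT_RISK,
    DEFAULT_THERMO,
    ActivityCoefficients,
    calibrate_ct,
)


@pytest.fixture(scope="session")
def thermo():
    return DEFAULT_THERMO


@pytest.fixture(scope="session")
def risk_params():
    return DEFAULT_RISK


@pytest.fixture(scope="session")
def unity():
    return ActivityCoefficients.unity()


@pytest.fixture(scope="session")
def ct_cal(thermo, unity):
    """Anchor-calibrated total inorganic carbon (mol/L)."""
    return calibrate_ct(thermo, unity)


@pytest.fixture(scope="session")
def ph_grid_dense():
    return np.linspace(0.5, 13.5, 1000)
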