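import numpy as np
import pytest

from gpresem import fit_ml, triticale_gpre_model, triticale_moments


@pytest.fixture(scope="session")
def gpre_model():
    return triticale_gpre_model()


@pytest.fixture(scope="session")
def gpre_moments():
    """ML-divisor covariance reconstructed from the packaged fixtures."""
    return triticale_moments(divisor="n")


@pytest.fixture(scope="session")
def gpre_fit(gpre_model, gpre_moments):
    return fit_ml(gpre_model, gpre_moments)


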