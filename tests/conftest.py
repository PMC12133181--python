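import numpy as np
import pytest

from karyodyn import builtin_designs
from karyodyn.karyotype import RateSet, ViabilityScheme


@pytest.fixture(scope="session")
def designs():
    return builtin_designs()


@pytest.fixture(scope="session")
def paper_rates():
    """Rates at the published point estimates."""
    return RateSet(mu_f=1.49e-3, mu_m=5.79e-4,
                   lambda_f=6.30e-3, lambda_m=5.50e-5)


@pytest.fixture
def default_scheme():
    return ViabilityScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
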