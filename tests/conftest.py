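import numpy as np
import pytest

from taueff import SpectralDensityModel, make_field


@pytest.fixture
def field600():
    return make_field(600.0)


@pytest.fixture
def field500():
    return make_field(500.0)


def random_mixture(rng: np.random.Generator, max_components: int = 8,
                   tau_lo: float = 1e-12, tau_hi: float = 2e-7
                   ) -> SpectralDensityModel:
    """Random normalized multi-exponential model (log-uniform timescales)."""
    n = int(rng.integers(1, max_components + 1))
    taus = 10.0 ** rng.uniform(np.log10(tau_lo), np.log10(tau_hi), size=n)
    weights = rng.dirichlet(np.ones(n))
    return SpectralDensityModel.from_components(weights, taus)
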