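import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cbfmap as cm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return cm.PipelineConfig()


@pytest.fixture(scope="session")
def fine_grid():
    """Interpolated-resolution time grid covering the 40-frame window."""
    return np.arange(0.0, 39 * 0.58 + 1e-9, 0.0116)


def classic_gamma(t, t0, alpha, beta, amplitude=1.0):
    """Unnormalized gamma-variate A*((t-t0)/beta)**a * exp(-(t-t0)/beta)."""
    t = np.asarray(t, dtype=float)
    x = np.maximum(t - t0, 0.0)
    return amplitude * (x / beta) ** alpha * np.exp(-x / beta)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default two-hemisphere scene without camera noise, with truth maps."""
    spec = cm.two_hemisphere_spec(noise_sigma=0.0, seed=7)
    return cm.generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom, config):
    stack, _truth = noiseless_phantom
    return cm.compute_maps(stack, config)
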