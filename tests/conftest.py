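import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bessel_cylinder_fraction(times, diffusivity, radius, n_terms=50):
    """Analytic remaining fraction of a uniformly loaded cylinder emptying
    into an absorbing boundary: sum_k (4/a_k^2) exp(-D a_k^2 t / R^2)."""
    from scipy.special import jn_zeros

    alpha = jn_zeros(0, n_terms)
    t = np.asarray(times, float)[:, None]
    return np.sum(4.0 / alpha**2 * np.exp(-diffusivity * alpha**2 * t / radius**2), axis=1)
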