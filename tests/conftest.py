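import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def grid_search_rss(times: np.ndarray, remaining: np.ndarray, n: int = 400) -> float:
    """Brute-force oracle: best two-pool RSS on an n x n logarithmic grid
    over a in [0.01, 0.99], k in [1e-4, 0.5]. Independent of the fitter."""
    a = np.exp(np.linspace(np.log(0.01), np.log(0.99), n))
    k = np.exp(np.linspace(np.log(1e-4), np.log(0.5), n))
    # model[i, j, m] = a_i * exp(-k_j * t_m) + (1 - a_i)
    decay = np.exp(-np.outer(k, times))  # (n, T)
    model = a[:, None, None] * decay[None, :, :] + (1.0 - a)[:, None, None]
    rss = np.sum((model - remaining) ** 2, axis=2)
    return float(rss.min())


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)
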