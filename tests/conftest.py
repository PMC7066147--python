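import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_windows():
    """The double-well umbrella benchmark: 17 windows (-210..-50 deg, 10 deg
    steps), k = 0.015 kcal/mol/deg^2, 50,000 Metropolis samples per window."""
    from groovestate.synthetic import default_double_well, sample_protocol
    from groovestate.wham import make_windows

    potential = default_double_well()
    centers = make_windows(-210.0, -50.0, 10.0)
    windows = sample_protocol(potential, centers, k=0.015, n_steps=50_000,
                              seed=1, burn_in=1000)
    return potential, windows


@pytest.fixture(scope="session")
def benchmark_pmf(benchmark_windows):
    from groovestate.wham import wham_pmf

    _, windows = benchmark_windows
    return wham_pmf(windows)


def rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_311)
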