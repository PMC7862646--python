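import numpy as np
import pytest

from densiswitch import SimConfig, SnapshotSeries, ThetaParams, simulate_series


@pytest.fixture(scope="session")
def small_dataset():
    """Short well-separated regime-switching run used across modules."""
    cfg = SimConfig(n_potential_base=100, kappa_base=0.4, p11=0.9, p22=0.9,
                    decay=0.95, n_windows=60, seed=5)
    return simulate_series(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_series(rng, T):
    """A tiny valid series with arbitrary (if implausible) counts."""
    n = rng.integers(2, 30, T)
    m = np.clip(rng.integers(1, 40, T), (n + 1) // 2, n * (n - 1) // 2)
    return SnapshotSeries(np.arange(T) * 600.0, n, m)


def random_theta(rng):
    return ThetaParams(
        n_potential=rng.uniform(25, 60),
        kappa=rng.uniform(0.1, 0.9),
        sigma1=rng.uniform(1, 8),
        sigma2=rng.uniform(1, 8),
        p11=rng.uniform(0.6, 0.98),
        p22=rng.uniform(0.6, 0.98),
    )
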