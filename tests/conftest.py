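import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catser.tracts import Tract, TractDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_tract(rng: np.random.Generator, tid: int = 0, n_points: int | None = None,
                 scale: float = 30.0) -> Tract:
    """A smooth random polyline: unit steps with a slowly rotating direction."""
    n = n_points or int(rng.integers(5, 25))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    steps = []
    for _ in range(n - 1):
        d = d + 0.15 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        steps.append(d.copy())
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + rng.uniform(0, scale, 3)
    return Tract(pts, tid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pairs(rng):
    """50 random tract pairs for property checks."""
    return [(random_tract(rng, 2 * i), random_tract(rng, 2 * i + 1)) for i in range(50)]


@pytest.fixture
def small_dataset(rng):
    return TractDataset([random_tract(rng, i) for i in range(20)])
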