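import numpy as np
import pytest

from unbendfish import AxisSpec, Dataset, LandmarkConfiguration, SimConfig, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


@pytest.fixture
def axis():
    return AxisSpec()


def random_dataset(rng, n=8, p=6, dispersion=0.25):
    """Random landmark dataset: perturbations of a shared base shape.

    Shapes scatter around a common configuration, as digitized specimens of
    one landmark scheme do; fully unrelated shapes would have no meaningful
    consensus.
    """
    base = rng.normal(size=(p, 2))
    configs = [
        LandmarkConfiguration(
            specimen_id=f"s{i}",
            coords=base + dispersion * rng.normal(size=(p, 2)),
            species="a" if i % 2 == 0 else "b",
        )
        for i in range(n)
    ]
    return Dataset(configs)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def synth_sample():
    """One medium simulated sample shared across tests (read-only)."""
    cfg = SimConfig(n_per_species=(30, 15), seed=7)
    return simulate_sample(cfg)


def similarity_transform(coords, rng, allow_scale=True):
    """Random rotation + translation (+ optional scaling) of a configuration."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    scale = rng.uniform(0.2, 5.0) if allow_scale else 1.0
    shift = rng.normal(scale=10.0, size=2)
    return scale * coords @ rot.T + shift
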