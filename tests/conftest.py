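import numpy as np
import pytest

from pharl import RunConfig, SimConfig, make_fixture, simulate_dataset


@pytest.fixture(scope="session")
def toy_labeling():
    return make_fixture("toy_labeling")


@pytest.fixture(scope="session")
def toy_relations():
    return make_fixture("toy_relations")


@pytest.fixture(scope="session")
def toy_training():
    return make_fixture("toy_training")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared by read-only tests."""
    cfg = SimConfig(n_trajectories=60, frames_per_trajectory=96, feature_dim=10,
                    seed=42)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture()
def tiny_run_config():
    """A pipeline config small enough for seconds-scale end-to-end runs."""
    cfg = RunConfig(seed=5).with_seed(5)
    cfg.sim = SimConfig(n_trajectories=40, frames_per_trajectory=64,
                        feature_dim=6, nuisance_dim=2, seed=cfg.sim.seed)
    cfg.train.epochs = 3
    cfg.relations.batch_size = 32
    return cfg


def random_unit_rows(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
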