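import numpy as np
import pytest

from glocalsvm import (
    KernelSpec,
    LabeledDataset,
    SynthConfig,
    fit_lssvm,
    generate_synthetic,
)


@pytest.fixture
def two_point_data() -> LabeledDataset:
    """The solvable-by-hand problem: x1=(0,0) y=+1, x2=(1,0) y=-1."""
    return LabeledDataset([[0.0, 0.0], [1.0, 0.0]], [1.0, -1.0], [0, 1])


@pytest.fixture
def two_point_model(two_point_data):
    """Linear kernel, gamma=1, raw features: alpha=(2/3, 2/3), b=1/3."""
    return fit_lssvm(two_point_data, KernelSpec("linear"), 1.0, standardize=False)


@pytest.fixture
def blobs() -> LabeledDataset:
    """Two well-separated Gaussian blobs, 30 points each."""
    rng = np.random.default_rng(42)
    a = rng.normal(loc=(-5.0, 0.0), scale=0.3, size=(30, 2))
    b = rng.normal(loc=(5.0, 0.0), scale=0.3, size=(30, 2))
    X = np.vstack([a, b])
    y = np.concatenate([np.ones(30), -np.ones(30)])
    return LabeledDataset(X, y, np.arange(60))


@pytest.fixture(scope="session")
def small_benchmark() -> LabeledDataset:
    """A 1,000-point draw of the imbalanced synthetic benchmark."""
    return generate_synthetic(SynthConfig(n_total=1_000, seed=7))


def random_small_problem(rng: np.random.Generator, n_max: int = 50) -> LabeledDataset:
    """Random small binary dataset with both classes guaranteed."""
    n = int(rng.integers(4, n_max + 1))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[0], y[1] = 1.0, -1.0
    return LabeledDataset(X, y, np.arange(n))
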