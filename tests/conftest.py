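import numpy as np
import pytest

from toxcascade import (
    CascadeConfig,
    FrameworkConfig,
    SynthSpec,
    generate_collection,
)


@pytest.fixture(scope="session")
def tiny_cascade_config():
    """Small cascade for fast unit tests (not the production defaults)."""
    return CascadeConfig(trees_per_unit=10, cv_folds=3, max_layers=3, seed=7)


@pytest.fixture(scope="session")
def tiny_framework_config(tiny_cascade_config):
    return FrameworkConfig(cascade=tiny_cascade_config, seed=7)


@pytest.fixture(scope="session")
def small_collection():
    """Three related tasks, pre-split, small enough for second-scale fits."""
    spec = SynthSpec(
        T=3, sizes=(60, 60, 60), d=12, n_clusters=1,
        relatedness=0.9, feature_sparsity=0.3, noise_sd=0.3, seed=11,
    )
    return generate_collection(spec)


@pytest.fixture()
def nonlinear_regression():
    """Gaussian-feature regression with an interaction term."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 10))
    y = X[:, 0] + X[:, 1] * X[:, 2] + rng.normal(scale=0.2, size=200)
    return X, y
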