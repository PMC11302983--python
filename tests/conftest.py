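import numpy as np
import pytest

from effsyn.datasets import make_classification_task
from effsyn.network import NetworkConfig


@pytest.fixture(scope="session")
def ci_dataset():
    """The desk-scale study task: 4 classes, 100 rate-heterogeneous features."""
    return make_classification_task(
        n_classes=4, n_features=100, n_samples=4000, rate_heterogeneity=3.0, seed=0
    )


@pytest.fixture(scope="session")
def ci_network():
    return NetworkConfig((100, 32, 32, 4))


@pytest.fixture(scope="session")
def micro_dataset():
    """A very small task for fast plumbing tests."""
    return make_classification_task(
        n_classes=3, n_features=20, n_samples=600, rate_heterogeneity=1.5, seed=1
    )


@pytest.fixture(scope="session")
def micro_network():
    return NetworkConfig((20, 8, 8, 3))
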