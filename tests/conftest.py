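import numpy as np
import pytest

from neurotune import SearchSpace, make_synthetic_dataset


@pytest.fixture
def unit_space():
    return SearchSpace(lower=np.zeros(3), upper=np.ones(3))


@pytest.fixture(scope="session")
def tiny_binary_frame():
    """Small binary dataset for fast training tests (~3,000 instances)."""
    frame, _ = make_synthetic_dataset(
        n_classes=2, windows_per_class=10, channels=4, seed=7,
    )
    return frame


@pytest.fixture(scope="session")
def tiny_multiclass_frame():
    frame, _ = make_synthetic_dataset(
        n_classes=3, windows_per_class=6, channels=4, seed=7,
    )
    return frame
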