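import numpy as np
import pytest

from omiclust import SyntheticSpec, generate_multiomics


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def standard_bundle():
    """The default well-separated two-view cohort (N=60, K=3)."""
    return generate_multiomics(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def quick_fit_kwargs():
    """Reduced epoch counts for pipeline smoke tests."""
    return dict(warmup_epochs=30, train_epochs=60, finetune_start=30)
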