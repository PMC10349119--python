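import numpy as np
import pytest

from ramanclass import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hw_effect_dataset():
    """Small two-class set separable only through the CH band at 2934 cm^-1."""
    cfg = syn.two_class_config("hw", delta=1.5, n_per_class=100, seed=7, outlier_rate=0.0)
    return syn.generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Small two-class set with identically distributed classes."""
    cfg = syn.two_class_config(None, n_per_class=100, seed=11, outlier_rate=0.0)
    return syn.generate_dataset(cfg)
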