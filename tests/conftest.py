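import numpy as np
import pytest

from histofuse import synthfix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gradient_image():
    """64x64 horizontal intensity ramp covering [0, 252]."""
    return np.tile(np.arange(64, dtype=float) * 4, (64, 1))


@pytest.fixture
def small_feature_triplet():
    """Scaled-down correlated feature triplet with 10 planted columns."""
    spec = synthfix.SynthFeatureSpec(
        n_per_class=30, dim=60, n_informative=10, class_shift=1.5,
        correlation=0.7, seed=7,
    )
    return synthfix.make_feature_triplet(spec)
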