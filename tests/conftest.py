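import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def feature_dataset():
    """The 50-feature / 5-informative selection benchmark."""
    from hybwave import synthetic
    spec = synthetic.FeatureSpec(seed=42)
    X, y, mask = synthetic.make_feature_dataset(spec)
    return X, y, mask


@pytest.fixture(scope="session")
def rect_phantom():
    """Piecewise-constant rectangle phantom + 10% Gaussian noise, seeded."""
    im = np.zeros((64, 64))
    im[20:40, 15:45] = 1.0
    rng = np.random.default_rng(0)
    noisy = im + rng.normal(0.0, 0.1, im.shape)
    return im, noisy
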