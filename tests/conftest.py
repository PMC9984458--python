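import numpy as np
import pytest

from cmsfl import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def easy_dataset():
    """Three well-separated classes, 10 images each, 32px — shared fixture."""
    spec = SyntheticSpec(
        n_classes=3, counts_per_class=(10, 10, 10), image_side=32,
        noise_sd=0.02, difficulty=0.0, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
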