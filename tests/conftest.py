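import numpy as np
import pytest

from btfsc.phantom import PhantomSpec, generate_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def malignant_pair():
    spec = PhantomSpec(
        tumor_class="malignant", boundary_irregularity=0.35, texture_amplitude=0.15,
        noise_sigma=10.0, seed=1,
    )
    return generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def benign_pair():
    return generate_phantom_pair(PhantomSpec(noise_sigma=10.0, seed=1))


@pytest.fixture(scope="session")
def small_pairs():
    """Eight noisier phantoms for fusion/training smoke tests."""
    from btfsc.phantom import generate_labeled_dataset

    return generate_labeled_dataset(8, 0.5, 3)
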