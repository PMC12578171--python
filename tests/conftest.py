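import numpy as np
import pytest

from ccfmcaps import ClassArchetype, LeafImageSpec, generate


@pytest.fixture(scope="session")
def tiny_leaf_set():
    """Small 16x16 two-class leaf set for fast network tests."""
    spec = LeafImageSpec(
        classes=[
            ClassArchetype("healthy", 10, leaf_rgb=(0.15, 0.58, 0.18)),
            ClassArchetype("spotted", 10, leaf_rgb=(0.30, 0.50, 0.15),
                           lesion_rgb=(0.55, 0.30, 0.08), n_lesions=(3, 5)),
        ],
        image_size=(16, 16), noise_sigma=0.02, seed=11)
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
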