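import numpy as np
import pytest

from leafmoe.synth import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def small_lab_set():
    """3 classes x 12 images, lab domain — cheap shared fixture."""
    return generate_dataset(SyntheticDatasetSpec(n_classes=3, images_per_class=12,
                                                 seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
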