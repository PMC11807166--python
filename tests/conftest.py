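import numpy as np
import pytest

from gafs import SyntheticSpec, generate_dataset, split_dataset


@pytest.fixture
def planted_ds():
    """Small planted dataset with train/val/test split: 4 informative
    (separation 5), 4 redundant copies, 16 noise, 3 classes, 150 rows."""
    spec = SyntheticSpec(
        n_samples=150,
        n_classes=3,
        n_informative=4,
        n_redundant=4,
        n_noise=16,
        class_separation=5.0,
        seed=11,
    )
    return split_dataset(generate_dataset(spec), (0.7, 0.2, 0.1), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
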