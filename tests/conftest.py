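import numpy as np
import pytest

from toothset import generate_dataset, separable_preset


@pytest.fixture(scope="session")
def small_separable_dataset():
    """16-specimen in-memory dataset on the 4-class separable preset."""
    return generate_dataset(
        separable_preset(), n_per_class=4, train_fraction=0.75, seed=7,
        size=(96, 72), noise_level=2.0,
    )


@pytest.fixture(scope="session")
def tooth_counts():
    """A class-balanced-ish fine-class count table used across tests."""
    counts = [55, 52, 50, 50, 54, 63, 49, 51, 53, 53, 54, 52, 57, 54, 45, 58]
    classes = [f"U{i}" for i in range(1, 9)] + [f"L{i}" for i in range(1, 9)]
    return dict(zip(classes, counts))
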