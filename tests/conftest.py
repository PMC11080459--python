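import numpy as np
import pytest

import metabarcode as mb
from metabarcode.grid import model_grid


@pytest.fixture(scope="session")
def grid():
    return model_grid()


@pytest.fixture(scope="session")
def barcode():
    return mb.build_target_barcode()


@pytest.fixture(scope="session")
def layout(barcode):
    return mb.double_and_randomize(barcode, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-contrast dataset shared by classifier unit tests."""
    return mb.generate_labeled_dataset(n_per_class=40, seed=7)


@pytest.fixture(scope="session")
def tiny_rng():
    return np.random.default_rng(1234)
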