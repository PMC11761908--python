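import numpy as np
import pytest

from dsunet.io_preprocess import BoxCoxParams, preprocess_dataset
from dsunet.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small preprocessed 32x32 synthetic dataset shared across tests.

    12 images per class per modality (48 total), 80:20 split.
    """
    root = tmp_path_factory.mktemp("small_ds")
    manifest = generate_dataset(12, 32, seed=11, out_dir=root / "raw")
    processed = preprocess_dataset(manifest, BoxCoxParams(), 32, root / "proc")
    return processed


@pytest.fixture
def rng():
    return np.random.default_rng(0)
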