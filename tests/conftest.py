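import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from habitomics.phantom import PhantomParams, generate_phantom
from habitomics.preprocess import PreprocessConfig, preprocess_volumeset


@pytest.fixture(scope="session")
def small_phantom():
    """A 3-habitat phantom on a small grid (shared, read-only)."""
    params = PhantomParams(grid_shape=(22, 22, 16), seed=42)
    vs, truth = generate_phantom(params, msi=0)
    return vs, truth


@pytest.fixture(scope="session")
def preprocessed(small_phantom):
    vs, _ = small_phantom
    return preprocess_volumeset(vs, PreprocessConfig(bias_correction=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
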