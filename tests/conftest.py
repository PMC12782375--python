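import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dffs_qsar import DescriptorMatrix, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across read-only tests."""
    cfg = SyntheticConfig(
        n_compounds=400,
        n_descriptors=60,
        n_informative_activity=6,
        n_informative_admet=9,
        n_constant_zero=3,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_matrix():
    values = np.array(
        [
            [1.0, 0.0, 2.0, 3.7],
            [2.0, 0.0, 4.0, 3.7],
            [3.0, 0.0, 6.0, 3.7],
        ]
    )
    return DescriptorMatrix(
        ["a", "b", "c"], ["d1", "zeros", "d2", "const"], values
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
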