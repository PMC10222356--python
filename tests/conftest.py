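import numpy as np
import pytest

from sleepfusion.psg_io import EpochSet
from sleepfusion.synthetic_data import SyntheticConfig, generate_epochset


@pytest.fixture(scope="session")
def small_epochset() -> EpochSet:
    """Ten 30 s epochs per stage at the standard 100 Hz, easy separability."""
    return generate_epochset(SyntheticConfig(epochs_per_class=10, seed=42))


@pytest.fixture(scope="session")
def tiny_epochset() -> EpochSet:
    """Short (1 s) epochs for fast training-loop tests; full channel layout."""
    return generate_epochset(
        SyntheticConfig(epochs_per_class=8, seed=7, epoch_len_s=1.0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
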