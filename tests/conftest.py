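import numpy as np
import pandas as pd
import pytest

from farmnet import AsvTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """2 samples x 3 ASVs with hand-checkable values."""
    counts = pd.DataFrame(
        [[5, 1, 0], [0, 2, 7]], index=["s1", "s2"], columns=["a", "b", "c"]
    )
    return AsvTable(counts)


@pytest.fixture
def random_table(rng):
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(12, 30)),
        index=[f"s{i}" for i in range(12)],
        columns=[f"asv{j}" for j in range(30)],
    )
    return AsvTable(counts)


def make_meta_table(counts, niches, treatments, amplicon="16S"):
    """Attach minimal metadata to a counts frame."""
    meta = pd.DataFrame(
        {"niche": niches, "treatment": treatments, "amplicon": amplicon},
        index=counts.index,
    )
    return AsvTable(counts, meta)
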