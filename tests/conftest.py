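import functools

import numpy as np
import pandas as pd
import pytest

from raretaxa import synth
from raretaxa.io import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        [[5, 0, 3], [2, 2, 0], [1, 1, 1]],
        index=["s1", "s2", "s3"], columns=["o1", "o2", "o3"],
    )
    return OtuTable(counts)


@functools.cache
def _scenario(name: str):
    return synth.generate_community(synth.scenario_presets()[name])


@pytest.fixture(scope="session")
def scenario():
    """Factory for preset scenarios, generated once per session."""
    return _scenario


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=(10, 30))
    return OtuTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(10)],
        columns=[f"o{i}" for i in range(30)],
    ))
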