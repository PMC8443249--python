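import numpy as np
import pytest

from condoverlap import DifferentialTable


def make_table(p_values, lfc=None, ids=None, name=""):
    """Build a DifferentialTable from plain sequences."""
    p = np.asarray(p_values, dtype=float)
    if ids is None:
        ids = [f"f{i:05d}" for i in range(len(p))]
    return DifferentialTable.from_arrays(ids, p, lfc=lfc, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_table(rng):
    """2,000 features with exchangeable (uniform) p-values."""
    return make_table(rng.uniform(size=2000), lfc=rng.normal(0, 0.5, 2000),
                      name="uniform")
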