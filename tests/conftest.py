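import numpy as np
import pytest

from hepatwin.grid import TimeGrid, default_grid
from hepatwin.tensor import ExpressionTensor


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def small_grid():
    """Baseline + four post-operative points."""
    return TimeGrid(
        labels=("Before Surgery", "2 h", "1 d", "10 d", "3 mo"),
        hours=(0.0, 2.0, 24.0, 240.0, 2190.0),
    )


def make_tensor(values, scale="raw", mask=None, genes=None, patients=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    g, p, _ = values.shape
    return ExpressionTensor(
        values, mask, scale,
        genes or tuple(f"g{i}" for i in range(g)),
        patients or tuple(f"p{i}" for i in range(p)),
    )


@pytest.fixture
def tensor_factory():
    return make_tensor
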