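import numpy as np
import pytest

from ringpta.datacube import Mode, RingDatacube, TableStack
from ringpta.preprocess import standardize_stack


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_cube(n=5, p=3, T=4, seed=0, with_coords=True):
    """Small random complete cube with labeled axes."""
    rng = np.random.default_rng(seed)
    return RingDatacube(
        values=rng.standard_normal((n, p, T)),
        tree_ids=[f"T{i}" for i in range(n)],
        descriptor_names=[f"D{j}" for j in range(p)],
        years=list(range(1990, 1990 + T)),
        coords=rng.uniform(0, 50, size=(n, 2)) if with_coords else None,
    )


def make_std_stack(K=3, rows=6, p=3, seed=0, mode=Mode.BY_YEAR):
    """Random standardized stack (population-sd convention)."""
    rng = np.random.default_rng(seed)
    raw = TableStack(
        mode=mode,
        tables=[rng.standard_normal((rows, p)) for _ in range(K)],
        table_keys=list(range(K)),
        row_keys=[f"r{i}" for i in range(rows)],
        col_names=[f"D{j}" for j in range(p)],
    )
    return standardize_stack(raw)


@pytest.fixture
def small_cube():
    return make_cube()


@pytest.fixture
def std_stack():
    return make_std_stack()
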