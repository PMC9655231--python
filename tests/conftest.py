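import numpy as np
import pytest

import hotgrid as hg


@pytest.fixture(scope="session")
def grid30x40():
    return hg.build_regular_grid(30, 40)


@pytest.fixture()
def grid5x5():
    return hg.build_regular_grid(5, 5)


@pytest.fixture()
def field_1_to_25():
    """Fixed 5x5 field with values 1..25 row-major."""
    return hg.CellField(np.arange(1.0, 26.0))


@pytest.fixture()
def planted_8x8():
    """8x8 grid with a 2x2 block of value 50 amid value 1."""
    lattice = hg.build_regular_grid(8, 8)
    values = np.ones(64)
    block = np.array([3 * 8 + 3, 3 * 8 + 4, 4 * 8 + 3, 4 * 8 + 4])
    values[block] = 50.0
    return lattice, hg.CellField(values), block
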