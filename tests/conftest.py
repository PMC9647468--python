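import numpy as np
import pytest

from nutriscreen import ContingencyTable2x2


@pytest.fixture
def nrs_table() -> ContingencyTable2x2:
    """Published NRS-2002 arm index-vs-reference counts (n=244)."""
    return ContingencyTable2x2(tp=34, fp=47, fn=8, tn=155)


@pytest.fixture
def pg_table() -> ContingencyTable2x2:
    """Published PG-SGA-SF arm index-vs-reference counts (n=244)."""
    return ContingencyTable2x2(tp=49, fp=66, fn=9, tn=120)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_tables(rng: np.random.Generator, n_tables: int, low: int = 1, high: int = 200):
    """Random strictly positive 2x2 tables (all denominators defined)."""
    cells = rng.integers(low, high, size=(n_tables, 4))
    return [ContingencyTable2x2(*map(int, row)) for row in cells]
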