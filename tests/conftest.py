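import numpy as np
import pytest

from sarmatrix.matrix_builder import build_matrices_from_records
from sarmatrix.synthetic_data import demo_screen


@pytest.fixture(scope="session")
def demo_records():
    """Nine-compound demo fragment table (3 cores x 4 values)."""
    return demo_screen()


@pytest.fixture()
def demo_matrix(demo_records):
    (m,) = build_matrices_from_records(demo_records)
    return m


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
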