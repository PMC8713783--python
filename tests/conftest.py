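import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from loccsn import ExpressionMatrix


def make_expr(values, cell_type=None, pseudotime=None):
    """ExpressionMatrix with auto-generated IDs from a raw array."""
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=[f"c{i}" for i in range(c)],
        cell_type=None if cell_type is None else np.asarray(cell_type, dtype=object),
        pseudotime=pseudotime,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_positive_expr(rng):
    """30 cells x 4 genes of continuous positive expression."""
    return make_expr(np.exp(0.5 * rng.standard_normal((4, 30))))
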