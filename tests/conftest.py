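import numpy as np
import pandas as pd
import pytest

from genetclock.clock import PAIR_COLUMNS


def make_pair_table(rows):
    """Pair table from (chrom, pos, nd, na, td, ta) tuples."""
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def passing_rows(n, start_pos=1):
    """n records that pass the default VRF50 filters."""
    return [("c1", start_pos + i, 30, 0, 100, 60) for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
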