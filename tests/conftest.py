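import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from barniche.geo_io import EnvGrid
from barniche.trees import DatedTree


@pytest.fixture
def small_grid() -> EnvGrid:
    """5x4 grid with one nodata cell, values 10..29 row-major."""
    values = np.arange(20, dtype=float).reshape(5, 4) + 10.0
    mask = np.zeros((5, 4), dtype=bool)
    mask[4, 3] = True
    values[4, 3] = np.nan
    return EnvGrid(
        variable="temperature",
        values=values,
        nodata_mask=mask,
        xllcorner=-65.0,
        yllcorner=-30.0,
        cell_size=0.5,
    )


@pytest.fixture
def three_tip_tree() -> DatedTree:
    """((A:1,B:1):1,C:2); root age 2, one internal node age 1."""
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree() -> DatedTree:
    return DatedTree.from_newick(
        "(((A:0.5,B:0.5):1.0,(C:0.8,D:0.8):0.7):0.5,E:2.0);"
    )
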