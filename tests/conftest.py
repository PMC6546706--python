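import numpy as np
import pytest

from myoconnect.scrna import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_counts():
    """Hand-enumerated 6-gene x 5-cell matrix exercising the QC boundaries.

    Gene filter (count > 1 in >= 3 cells): keeps g0 (2,2,2,0,0),
    g3 (5,0,5,5,5), g5 (3,3,3,3,3); drops g1 (only 2 qualifying cells),
    g2 (counts of 1 are not > 1), g4 (all zero).
    After gene filtering, cells express (count > 0): c0 -> 3 genes,
    c1 -> 2, c2 -> 3, c3 -> 2, c4 -> 2.
    """
    counts = np.array([
        [2, 2, 2, 0, 0],   # g0: kept
        [2, 2, 0, 0, 0],   # g1: dropped (2 cells)
        [1, 1, 1, 1, 1],   # g2: dropped (1 is not > 1)
        [5, 0, 5, 5, 5],   # g3: kept
        [0, 0, 0, 0, 0],   # g4: dropped
        [3, 3, 3, 3, 3],   # g5: kept
    ])
    return CountMatrix(counts=counts,
                       gene_ids=[f"g{i}" for i in range(6)],
                       cell_ids=[f"c{i}" for i in range(5)])
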