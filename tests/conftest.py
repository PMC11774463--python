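import numpy as np
import pytest

from ccmotif.motif import Motif
from ccmotif.synthetic import random_cell_table, random_triangulated_graph


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def triangle_cells():
    import pandas as pd
    return pd.DataFrame({
        "cell_id": ["a", "b", "c"],
        "x": [0.0, 1.0, 0.5],
        "y": [0.0, 0.0, 1.0],
        "cell_type": ["A", "B", "C"],
    })


@pytest.fixture(scope="session")
def medium_graph():
    """60-node triangulated graph with 4 cell types."""
    return random_triangulated_graph(60, 4, seed=7)


@pytest.fixture(scope="session")
def small_graphs():
    """A handful of small labeled triangulated graphs for oracle checks."""
    return [random_triangulated_graph(n, t, seed=s)
            for s, (n, t) in enumerate([(8, 2), (10, 3), (12, 3),
                                        (14, 4), (16, 4)])]


@pytest.fixture(scope="session")
def motif_zoo():
    """Motifs of sizes 1-5 over the synthetic alphabet."""
    t = [f"t{i:02d}" for i in range(4)]
    tri = [(0, 1), (1, 2), (0, 2)]
    return [
        Motif([t[0]], []),
        Motif([t[0], t[1]], [(0, 1)]),
        Motif([t[0], t[0], t[1]], tri),
        Motif([t[0], t[1], t[2]], tri),
        Motif([t[0], t[1], t[2], t[3]], tri + [(1, 3), (2, 3)]),
        Motif([t[0], t[0], t[1], t[2], t[3]],
              tri + [(1, 3), (2, 3), (2, 4), (3, 4)]),
    ]


@pytest.fixture
def cells_500():
    rng = np.random.default_rng(11)
    return random_cell_table(500, 5, rng)
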