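import numpy as np
import pytest

from zooregion.incidence import OGU, AdjacencyGraph, IncidenceMatrix, SpeciesRecord


@pytest.fixture
def toy_matrix():
    """3 species x 2 OGUs with row sums [1, 1, 2]."""
    return IncidenceMatrix(
        ["sp1", "sp2", "sp3"], ["A", "B"], np.array([[1, 0], [0, 1], [1, 1]])
    )


@pytest.fixture
def five_ogu_matrix():
    """5 OGUs in a path A-B-C-D-E; two assemblage blocks {A,B} and {D,E}."""
    ogus = ["A", "B", "C", "D", "E"]
    cells = np.array(
        [
            [1, 1, 0, 0, 0],  # west pair
            [1, 1, 0, 0, 0],
            [1, 0, 0, 0, 0],  # singleton in A
            [0, 0, 1, 1, 1],  # east block
            [0, 0, 0, 1, 1],
            [0, 0, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return IncidenceMatrix([f"s{i}" for i in range(1, 7)], ogus, cells)


@pytest.fixture
def path_graph():
    ogus = ["A", "B", "C", "D", "E"]
    return AdjacencyGraph(ogus, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_incidence(rng, n_species, n_ogus, p=0.3):
    cells = (rng.random((n_species, n_ogus)) < p).astype(np.int8)
    # avoid empty species rows for distance-based code
    for i in range(n_species):
        if cells[i].sum() == 0:
            cells[i, rng.integers(n_ogus)] = 1
    return IncidenceMatrix(
        [SpeciesRecord(f"s{i}") for i in range(n_species)],
        [OGU(f"U{j:02d}") for j in range(n_ogus)],
        cells,
    )
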