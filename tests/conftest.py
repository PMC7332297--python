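import numpy as np
import pytest

from antmaze import synthetic_env as se
from antmaze import maze_geometry as mg


@pytest.fixture(scope="session")
def board():
    return se.BoardSpec()


@pytest.fixture(scope="session")
def empty_maze(board):
    return se.MazeConfig(board=board, cubes=())


@pytest.fixture(scope="session")
def single_cube_maze(board):
    return se.MazeConfig(board=board, cubes=((35.0, 25.0, 0.0),))


@pytest.fixture(scope="session")
def cup_maze():
    return se.make_toy_trap("cup", 6.0)


@pytest.fixture(scope="session")
def cup_grid(cup_maze):
    return mg.access_grid(cup_maze, 0.1)


@pytest.fixture(scope="session")
def medium_maze(board):
    """One fixed 250-cube maze shared by simulator tests."""
    return se.generate_cube_maze(250, board, seed=42)


@pytest.fixture(scope="session")
def medium_grid(medium_maze):
    return mg.access_grid(medium_maze, 0.1)


def dijkstra_oracle(accessible, cell_size, sources, targets=None):
    """Chamfer-metric multi-source Dijkstra on a boolean raster.

    Independent reference for every geodesic engine in the package:
    builds the 8-connected graph explicitly and runs scipy's Dijkstra.
    Returns the distance field (cm), inf where unreachable.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    ny, nx = accessible.shape
    idx = -np.ones((ny, nx), dtype=int)
    cells = np.argwhere(accessible)
    idx[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    rows, cols, data = [], [], []
    for dr, dc, w in [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]:
        r, c = cells[:, 0], cells[:, 1]
        r2, c2 = r + dr, c + dc
        ok = (r2 >= 0) & (r2 < ny) & (c2 >= 0) & (c2 < nx)
        ok[ok] &= accessible[r2[ok], c2[ok]]
        rows += [idx[r[ok], c[ok]]]
        cols += [idx[r2[ok], c2[ok]]]
        data += [np.full(ok.sum(), w * cell_size)]
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(cells), len(cells)),
    )
    src = [idx[r, c] for r, c in sources if idx[r, c] >= 0]
    dist = dijkstra(graph, directed=False, indices=src, min_only=True)
    field = np.full((ny, nx), np.inf)
    field[cells[:, 0], cells[:, 1]] = dist
    return field
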