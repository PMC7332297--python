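"""Configuration-space geometry of the disc load over continuous cube mazes.

The load is a disc of radius ``R``; its configuration space is the board
minus the Minkowski sum of every cube footprint with a disc of radius ``R``
(dilated squares with rounded corners) and minus an ``R``-wide margin along
the three walls (the nest edge, ``x = width``, is open).  All geometric
questions — coverage, solvability, geodesic shortest paths, the continuous
percolation curve — are answered on a boolean raster of this space.

Conventions fixed here and shared by every module:

* origin at the start corner, ``+x`` toward the nest (the bias direction);
  the load starts at ``(0, height/2)``,
* raster cell centers at ``((col + 1/2) h, (row + 1/2) h)`` with default
  cell size ``h = 0.1`` cm (the discrete walker's step),
* 8-connectivity for both accessible space and obstacle blobs,
* geodesics are 8-connected chamfer paths (diagonal step ``sqrt(2) h``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .synthetic_env import BoardSpec, MazeConfig, generate_cube_maze

__all__ = [
    "AccessGrid",
    "PathResult",
    "StartUnreachableError",
    "access_grid",
    "coverage",
    "is_solvable",
    "shortest_path",
    "geodesic_distance",
    "percolation_curve",
    "START_SNAP_RADIUS",
]

#: snapping radius (cm) for inaccessible start positions
START_SNAP_RADIUS = 2.0

_EIGHT = np.ones((3, 3), dtype=bool)


class StartUnreachableError(RuntimeError):
    """No accessible cell within the snapping radius of the start point."""


@dataclass(frozen=True)
class AccessGrid:
    """Boolean raster of load-center positions, with its provenance masks.

    ``accessible`` marks cells the load center may occupy; it is the
    complement of ``cube_blocked | wall_margin``.  ``cube_blocked`` holds
    only cube-induced inaccessibility (the dilated obstacle field), which
    is what coverage and trap decomposition operate on.
    """

    board: BoardSpec
    cell_size: float
    accessible: np.ndarray = field(repr=False)
    cube_blocked: np.ndarray = field(repr=False)
    wall_margin: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.accessible.shape

    def x_of_col(self, col) -> np.ndarray:
        return (np.asarray(col) + 0.5) * self.cell_size

    def y_of_row(self, row) -> np.ndarray:
        return (np.asarray(row) + 0.5) * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Raster cell containing the point ``(x, y)`` (clipped to bounds)."""
        ny, nx = self.accessible.shape
        col = min(max(int(x / self.cell_size), 0), nx - 1)
        row = min(max(int(y / self.cell_size), 0), ny - 1)
        return row, col

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.accessible.shape
        return self.x_of_col(np.arange(nx)), self.y_of_row(np.arange(ny))


@dataclass(frozen=True)
class PathResult:
    """A raster geodesic: ordered waypoints (cm), its arc length, feasibility."""

    waypoints: np.ndarray
    arc_length: float
    feasible: bool


def _raster_shape(board: BoardSpec, cell_size: float) -> tuple[int, int]:
    return (
        int(math.ceil(board.height / cell_size - 1e-9)),
        int(math.ceil(board.width / cell_size - 1e-9)),
    )


def rasterize_cubes(maze: MazeConfig, cell_size: float) -> np.ndarray:
    """Cube-induced blocked mask: cell centers within ``R`` of a footprint.

    Each cube only touches a small window of the raster, so cubes are
    stamped one at a time with a vectorized point-to-square distance in the
    cube's own frame.
    """
    board = maze.board
    ny, nx = _raster_shape(board, cell_size)
    blocked = np.zeros((ny, nx), dtype=bool)
    if not maze.cubes:
        return blocked
    a, r = board.cube_edge, board.load_radius
    reach = a / math.sqrt(2.0) + r + cell_size
    half = a / 2.0
    for cx, cy, theta in maze.cubes:
        c0 = max(0, int((cx - reach) / cell_size))
        c1 = min(nx, int((cx + reach) / cell_size) + 1)
        r0 = max(0, int((cy - reach) / cell_size))
        r1 = min(ny, int((cy + reach) / cell_size) + 1)
        xs = (np.arange(c0, c1) + 0.5) * cell_size - cx
        ys = (np.arange(r0, r1) + 0.5) * cell_size - cy
        dx = xs[None, :]
        dy = ys[:, None]
        co, si = math.cos(theta), math.sin(theta)
        lx = co * dx + si * dy
        ly = -si * dx + co * dy
        ox = np.maximum(np.abs(lx) - half, 0.0)
        oy = np.maximum(np.abs(ly) - half, 0.0)
        blocked[r0:r1, c0:c1] |= ox * ox + oy * oy <= r * r
    return blocked


def access_grid(maze: MazeConfig, cell_size: float = 0.1) -> AccessGrid:
    """Rasterize the load's configuration space for one maze."""
    board = maze.board
    if cell_size > board.load_radius / 5 + 1e-12:
        raise ValueError("cell_size must be <= load_radius/5 for adequate resolution")
    ny, nx = _raster_shape(board, cell_size)
    cube_blocked = rasterize_cubes(maze, cell_size)
    xs = (np.arange(nx) + 0.5) * cell_size
    ys = (np.arange(ny) + 0.5) * cell_size
    r = board.load_radius
    # walls: x = 0 (start side), y = 0 and y = height; the nest edge is open
    margin = (
        (xs[None, :] < r) | (ys[:, None] < r) | (ys[:, None] > board.height - r)
    )
    margin = np.broadcast_to(margin, (ny, nx)).copy()
    accessible = ~(cube_blocked | margin)
    return AccessGrid(
        board=board, cell_size=cell_size,
        accessible=accessible, cube_blocked=cube_blocked, wall_margin=margin,
    )


def coverage(
    maze: MazeConfig, cell_size: float = 0.1, *, include_wall_margin: bool = True
) -> float:
    """Fraction of the board that is inaccessible to the load's center.

    With the default convention the numerator counts every inaccessible
    cell — the dilated cube field plus the ``R``-wide margins along the
    three walls — over the full board area, i.e. exactly the black area
    fraction of an accessibility image of the maze.  This is the
    convention under which randomly generated 300-cube boards average
    ~55% coverage and the solvability threshold sits at ~60%.

    ``include_wall_margin=False`` restricts the numerator to cube-induced
    inaccessibility outside the wall band, making coverage a property of
    the cube field alone (an empty maze then has coverage exactly 0, and
    one isolated cube contributes the closed-form dilated-square area
    ``(a+2R)^2 - (4-pi)R^2``).
    """
    board = maze.board
    ny, nx = _raster_shape(board, cell_size)
    cube_blocked = rasterize_cubes(maze, cell_size)
    xs = (np.arange(nx) + 0.5) * cell_size
    ys = (np.arange(ny) + 0.5) * cell_size
    r = board.load_radius
    margin = (xs[None, :] < r) | (ys[:, None] < r) | (ys[:, None] > board.height - r)
    if include_wall_margin:
        blocked = cube_blocked | np.broadcast_to(margin, (ny, nx))
    else:
        blocked = cube_blocked & ~margin
    return np.count_nonzero(blocked) * cell_size**2 / board.area


def _snap_to_accessible(grid: AccessGrid, start: tuple[float, float]) -> tuple[int, int]:
    row, col = grid.cell_of(*start)
    if grid.accessible[row, col]:
        return row, col
    w = int(math.ceil(START_SNAP_RADIUS / grid.cell_size))
    ny, nx = grid.shape
    r0, r1 = max(0, row - w), min(ny, row + w + 1)
    c0, c1 = max(0, col - w), min(nx, col + w + 1)
    cand = np.argwhere(grid.accessible[r0:r1, c0:c1])
    if cand.size == 0:
        raise StartUnreachableError("no accessible cell within 2 cm of the start")
    cand = cand + (r0, c0)
    d2 = (grid.y_of_row(cand[:, 0]) - start[1]) ** 2 + (
        grid.x_of_col(cand[:, 1]) - start[0]
    ) ** 2
    best = cand[int(np.argmin(d2))]
    if d2.min() > START_SNAP_RADIUS**2:
        raise StartUnreachableError("no accessible cell within 2 cm of the start")
    return int(best[0]), int(best[1])


def is_solvable(
    grid: AccessGrid,
    start: tuple[float, float] | None = None,
    goal: str = "right",
) -> bool:
    """True iff an 8-connected accessible path joins start to the goal edge."""
    if goal != "right":
        raise ValueError("only the nest ('right') edge is a supported goal")
    if start is None:
        start = (0.0, grid.board.height / 2.0)
    row, col = _snap_to_accessible(grid, start)
    labels, _ = ndimage.label(grid.accessible, structure=_EIGHT)
    start_label = labels[row, col]
    edge = labels[:, -1]
    return bool(np.any(edge == start_label))


def _mcp_costs(grid: AccessGrid) -> np.ndarray:
    costs = np.full(grid.shape, np.inf)
    costs[grid.accessible] = grid.cell_size
    return costs


def geodesic_distance(
    grid: AccessGrid, sources: np.ndarray, max_cost: float | None = None
) -> np.ndarray:
    """Chamfer geodesic distance transform (cm) from a set of source cells.

    ``sources`` is an ``(n, 2)`` array of (row, col).  Inaccessible cells
    and unreached cells are ``inf``.
    """
    mcp = MCP_Geometric(_mcp_costs(grid), fully_connected=True)
    costs, _ = mcp.find_costs(
        [tuple(map(int, s)) for s in np.atleast_2d(sources)],
        max_cost=max_cost,
    )
    return costs


def shortest_path(
    grid: AccessGrid, source_set: np.ndarray, target_set: np.ndarray
) -> PathResult:
    """Quasi-Euclidean geodesic between two cell sets on the raster.

    Both sets are ``(n, 2)`` arrays of (row, col) indices of accessible
    cells.  Infeasibility (disconnected sets) is a return state.
    """
    source_set = np.atleast_2d(np.asarray(source_set, int))
    target_set = np.atleast_2d(np.asarray(target_set, int))
    if source_set.size == 0 or target_set.size == 0:
        raise ValueError("source and target sets must be non-empty")
    for s in np.vstack([source_set, target_set]):
        if not grid.accessible[s[0], s[1]]:
            raise ValueError(f"cell {tuple(s)} is not accessible")
    mcp = MCP_Geometric(_mcp_costs(grid), fully_connected=True)
    costs, _ = mcp.find_costs(
        [tuple(map(int, s)) for s in source_set],
        ends=[tuple(map(int, t)) for t in target_set],
        find_all_ends=True,
    )
    target_costs = costs[target_set[:, 0], target_set[:, 1]]
    best = int(np.argmin(target_costs))
    if not np.isfinite(target_costs[best]):
        return PathResult(waypoints=np.empty((0, 2)), arc_length=math.inf, feasible=False)
    cells = np.asarray(mcp.traceback(tuple(target_set[best])))
    waypoints = np.column_stack(
        [grid.x_of_col(cells[:, 1]), grid.y_of_row(cells[:, 0])]
    )
    seg = np.diff(waypoints, axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return PathResult(waypoints=waypoints, arc_length=arc, feasible=True)


def percolation_curve(
    board: BoardSpec | None = None,
    cube_counts: list[int] | None = None,
    n_reps: int = 30,
    seed: int = 0,
    cell_size: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Solvable fraction vs. coverage over a cube-density sweep.

    For each cube count, ``n_reps`` seeded mazes are generated, their
    coverage measured, and solvability decided on the accessibility raster.
    The threshold estimate is the coverage at which a monotone (isotonic)
    fit of the solvable fraction crosses 0.5.

    Returns a ``(table, threshold)`` pair; the table has one row per cube
    count with columns ``cube_count, mean_coverage, solvable_fraction``.
    """
    board = board or BoardSpec()
    if cube_counts is None:
        cube_counts = [100, 150, 200, 250, 300, 350, 400, 450]
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for count in cube_counts:
        covs, solved = [], 0
        for rep in range(n_reps):
            sub = int(np.random.SeedSequence((seed, count, rep)).generate_state(1)[0])
            maze = generate_cube_maze(count, board, seed=sub)
            grid = access_grid(maze, cell_size)
            covs.append(
                np.count_nonzero(~grid.accessible) * cell_size**2 / board.area
            )
            try:
                solved += is_solvable(grid)
            except StartUnreachableError:
                pass
        rows.append(
            {
                "cube_count": count,
                "mean_coverage": float(np.mean(covs)),
                "solvable_fraction": solved / n_reps,
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_coverage", ignore_index=True)
    threshold = _crossing_coverage(
        table["mean_coverage"].to_numpy(), table["solvable_fraction"].to_numpy()
    )
    return table, threshold


def _crossing_coverage(cov: np.ndarray, frac: np.ndarray, level: float = 0.5) -> float:
    """Coverage where an isotonic (non-increasing) fit of ``frac`` crosses ``level``."""
    from sklearn.isotonic import IsotonicRegression

    fit = IsotonicRegression(increasing=False).fit(cov, frac).predict(cov)
    if fit.min() > level:
        return float("nan")
    if fit.max() < level:
        return float("nan")
    # first interval where the monotone curve passes through the level
    for i in range(len(cov) - 1):
        f0, f1 = fit[i], fit[i + 1]
        if f0 >= level >= f1:
            if f0 == f1:
                return float((cov[i] + cov[i + 1]) / 2)
            t = (f0 - level) / (f0 - f1)
            return float(cov[i] + t * (cov[i + 1] - cov[i]))
    return float(cov[np.argmin(np.abs(fit - level))])
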