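"""Trap decomposition and trap-depth statistics for cube mazes.

A maze's dilated obstacles form disjoint 8-connected blobs; a blob is a
*trap* if it blocks nest-ward (+x) motion for at least one accessible
position.  The depth ``D`` of a trap is the length of the escape geodesic
from its deepest point: over all blocked points ``q``,

    D = max_q [ geodesic(q, {accessible cells with x >= x_q + 3.2 cm}) - 3.2 ]

clipped at zero.  The 3.2 cm advance guarantees the trap is actually
cleared; trap-crossing trajectory segments use the same convention (start
1 cm ahead of the blob, end 3.2 cm past the entry x, deduct the 3.2 cm,
normalize by ``D``).

A point counts as blocked when blob cells sit within 0.25 cm directly
ahead of it in ``+x`` — the same forward-ray test that the bias-direction
field of the extended-sensing model applies, so trap membership and the
responsive machinery always agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.graph import MCP_Geometric
from skimage.measure import find_contours

from .maze_geometry import AccessGrid
from .synthetic_env import MazeConfig
from .trajectory import Trajectory

__all__ = [
    "ObstacleBlob",
    "Trap",
    "find_traps",
    "trap_depth",
    "difficult_fraction",
    "trap_crossing_stats",
    "BLOCK_RAY_LENGTH",
    "ESCAPE_ADVANCE",
]

#: forward-ray length (cm) of the blocked-point test
BLOCK_RAY_LENGTH = 0.25
#: nest-ward advance (cm) defining escape; deducted from escape geodesics
ESCAPE_ADVANCE = 3.2
#: trajectory is "at" a trap when within this distance (cm) of its blob
TRAP_APPROACH_DISTANCE = 1.0

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ObstacleBlob:
    """One 8-connected component of the dilated cube field."""

    label: int
    member_cubes: tuple[int, ...]
    cells: np.ndarray = field(repr=False)  # (n, 2) raster (row, col)
    boundary: np.ndarray = field(repr=False)  # (m, 2) cm polyline, closed


@dataclass(frozen=True)
class Trap:
    """A blob that blocks forward motion, with its escape depth.

    ``depth`` is in cm; ``inf`` marks blocked points from which the escape
    set is unreachable (sealed pockets).  ``escape_undefined`` flags traps
    abutting the nest edge, where the 3.2 cm advance leaves the board and
    no depth is defined.
    """

    blob: ObstacleBlob
    depth: float
    deepest_point: tuple[float, float] | None
    blocked_cells: np.ndarray = field(repr=False)  # (k, 2) raster (row, col)
    escape_undefined: bool = False

    @property
    def n_cubes(self) -> int:
        return len(self.blob.member_cubes)


def _blob_contour(mask: np.ndarray, cell_size: float, r0: int, c0: int) -> np.ndarray:
    """Longest iso-contour of a blob mask, in cm board coordinates."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:  # single-cell blob fallback
        return np.empty((0, 2))
    best = max(contours, key=len)
    rows = best[:, 0] - 1 + r0
    cols = best[:, 1] - 1 + c0
    return np.column_stack([(cols + 0.5) * cell_size, (rows + 0.5) * cell_size])


def label_blobs(maze: MazeConfig, grid: AccessGrid) -> tuple[np.ndarray, list[ObstacleBlob]]:
    """Label the dilated-cube mask and build one blob record per component."""
    labels, n_blobs = ndimage.label(grid.cube_blocked, structure=_EIGHT)
    members: dict[int, list[int]] = {}
    for i, (cx, cy, _) in enumerate(maze.cubes):
        lab = labels[grid.cell_of(cx, cy)]
        if lab > 0:
            members.setdefault(int(lab), []).append(i)
    blobs = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n_blobs + 1):
        sl = slices[lab - 1]
        mask = labels[sl] == lab
        cells = np.argwhere(mask) + (sl[0].start, sl[1].start)
        boundary = _blob_contour(mask, grid.cell_size, sl[0].start, sl[1].start)
        blobs.append(
            ObstacleBlob(
                label=lab,
                member_cubes=tuple(members.get(lab, ())),
                cells=cells,
                boundary=boundary,
            )
        )
    return labels, blobs


def blocking_labels(grid: AccessGrid, labels: np.ndarray) -> np.ndarray:
    """Label of the nearest blob within the forward ray of each cell (0 = none).

    Applies the 0.25 cm +x ray test to every raster cell; the result at
    accessible cells marks blocked points and identifies their trap.
    """
    k_max = int(math.floor(BLOCK_RAY_LENGTH / grid.cell_size + 1e-9))
    ahead = np.zeros_like(labels)
    for k in range(k_max, 0, -1):  # nearer columns overwrite farther ones
        ahead[:, :-k] = np.where(labels[:, k:] > 0, labels[:, k:], ahead[:, :-k])
    ahead[~grid.accessible] = 0
    return ahead


def find_traps(
    maze: MazeConfig, grid: AccessGrid, compute_depths: bool = True
) -> list[Trap]:
    """Decompose a maze into traps (one per blob with a blocked point).

    With ``compute_depths`` the escape geodesics of all blocked points are
    evaluated in one batched pass, grouped by raster column so that every
    group shares its escape set.
    """
    labels, blobs = label_blobs(maze, grid)
    ahead = blocking_labels(grid, labels)
    traps: list[Trap] = []
    blob_by_label = {b.label: b for b in blobs}
    blocked_by_label: dict[int, np.ndarray] = {}
    for lab in np.unique(ahead[ahead > 0]):
        blocked_by_label[int(lab)] = np.argwhere(ahead == lab)
    if not compute_depths:
        for lab, cells in blocked_by_label.items():
            traps.append(
                Trap(blob=blob_by_label[lab], depth=math.nan, deepest_point=None,
                     blocked_cells=cells)
            )
        return traps

    depth_map = _escape_distances(grid, ahead > 0)
    for lab, cells in blocked_by_label.items():
        d = depth_map[cells[:, 0], cells[:, 1]]
        if np.all(np.isnan(d)):
            traps.append(
                Trap(blob=blob_by_label[lab], depth=math.nan, deepest_point=None,
                     blocked_cells=cells, escape_undefined=True)
            )
            continue
        valid = ~np.isnan(d)
        dv, cv = d[valid], cells[valid]
        dmax = dv.max()
        # deterministic deepest point: smallest x, then smallest y
        at_max = cv[dv >= dmax - 1e-12]
        order = np.lexsort((at_max[:, 0], at_max[:, 1]))
        r, c = at_max[order[0]]
        traps.append(
            Trap(
                blob=blob_by_label[lab],
                depth=float(dmax),
                deepest_point=(float(grid.x_of_col(c)), float(grid.y_of_row(r))),
                blocked_cells=cells,
            )
        )
    return traps


def _escape_distances(grid: AccessGrid, blocked: np.ndarray) -> np.ndarray:
    """Escape depth for every blocked cell (NaN where undefined).

    For a cell in column ``c`` the escape set is all accessible cells with
    ``x >= x_c + 3.2``; any 8-connected path into that set enters through
    accessible cells of its first column, so the geodesic is computed as a
    multi-source chamfer distance from that single column, early-stopped
    at the column's blocked cells.
    """
    ny, nx = grid.shape
    h = grid.cell_size
    out = np.full((ny, nx), np.nan)
    cols = np.unique(np.nonzero(blocked)[1])
    costs = np.full((ny, nx), np.inf)
    costs[grid.accessible] = h
    # component bookkeeping lets sealed pockets skip the search entirely
    comp, _ = ndimage.label(grid.accessible, structure=_EIGHT)
    max_col = np.zeros(comp.max() + 1, dtype=int)
    rows_any, cols_any = np.nonzero(grid.accessible)
    np.maximum.at(max_col, comp[rows_any, cols_any], cols_any)
    shift = int(round(ESCAPE_ADVANCE / h))
    for c in cols:
        ends = np.nonzero(blocked[:, c])[0]
        ct = c + shift
        if ct >= nx:
            continue  # escape set empty: depth undefined for these cells
        start_rows = np.nonzero(grid.accessible[:, ct])[0]
        labels_q = comp[ends, c]
        reachable = (max_col[labels_q] >= ct) & np.isin(
            labels_q, np.unique(comp[start_rows, ct])
        )
        out[ends[~reachable], c] = np.inf
        ends = ends[reachable]
        if len(ends) == 0 or len(start_rows) == 0:
            out[ends, c] = np.inf
            continue
        mcp = MCP_Geometric(costs, fully_connected=True)
        cum, _ = mcp.find_costs(
            starts=[(int(r), int(ct)) for r in start_rows],
            ends=[(int(r), int(c)) for r in ends],
            find_all_ends=True,
        )
        out[ends, c] = np.maximum(cum[ends, c] - ESCAPE_ADVANCE, 0.0)
    return out


def trap_depth(trap: Trap, grid: AccessGrid) -> float:
    """Escape depth of a single trap (recomputed from its blocked cells)."""
    blocked = np.zeros(grid.shape, dtype=bool)
    blocked[trap.blocked_cells[:, 0], trap.blocked_cells[:, 1]] = True
    d = _escape_distances(grid, blocked)
    vals = d[trap.blocked_cells[:, 0], trap.blocked_cells[:, 1]]
    if np.all(np.isnan(vals)):
        return math.nan
    return float(np.nanmax(vals))


def difficult_fraction(
    mazes: list[MazeConfig],
    r_sense: float = 10.0,
    cell_size: float = 0.1,
    grids: list[AccessGrid] | None = None,
) -> tuple[float, float]:
    """Pooled difficult-trap statistics over a maze ensemble.

    Returns ``(difficult_cube_fraction, small_trap_fraction)``:

    * the fraction of all cubes that belong to traps deeper than
      ``r_sense`` (difficult traps), and
    * the fraction of traps with ``D <= r_sense`` out of all traps.

    Unreachable escapes (``D = inf``) count as difficult; traps whose
    depth is undefined (nest-edge abutment) are excluded.
    """
    from .maze_geometry import access_grid

    if not mazes:
        raise ValueError("need at least one maze")
    board = mazes[0].board
    if any(m.board != board for m in mazes):
        raise ValueError("all mazes must share a board")
    total_cubes = 0
    difficult_cubes = 0
    n_traps = 0
    n_small = 0
    for i, maze in enumerate(mazes):
        grid = grids[i] if grids is not None else access_grid(maze, cell_size)
        total_cubes += maze.n_cubes
        for trap in find_traps(maze, grid):
            if trap.escape_undefined:
                continue
            n_traps += 1
            if trap.depth <= r_sense:
                n_small += 1
            else:
                difficult_cubes += trap.n_cubes
    cube_frac = difficult_cubes / total_cubes if total_cubes else 0.0
    small_frac = n_small / n_traps if n_traps else math.nan
    return cube_frac, small_frac


def trap_crossing_stats(
    traj: Trajectory, trap: Trap
) -> tuple[bool, float] | None:
    """Clip a trajectory to one trap encounter and score the crossing.

    The segment begins when the path first comes within 1 cm of the
    trap's blob and ends when it has advanced 3.2 cm (in x) past the
    entry point; the 3.2 cm advance is deducted from the segment arc
    length and the remainder normalized by the trap depth ``D``.

    Returns ``None`` when the trajectory never approaches the trap, and
    ``(False, nan)`` when it terminates before clearing the trap.
    """
    if trap.blob.boundary.size == 0:
        return None
    tree = cKDTree(trap.blob.boundary)
    dist, _ = tree.query(traj.positions)
    near = np.nonzero(dist <= TRAP_APPROACH_DISTANCE)[0]
    if near.size == 0:
        return None
    i0 = int(near[0])
    x_exit = traj.x[i0] + ESCAPE_ADVANCE - 1e-9
    beyond = np.nonzero(traj.x[i0:] >= x_exit)[0]
    if beyond.size == 0:
        return False, math.nan
    i1 = i0 + int(beyond[0])
    seg = np.diff(traj.positions[i0 : i1 + 1], axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return True, (arc - ESCAPE_ADVANCE) / trap.depth
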