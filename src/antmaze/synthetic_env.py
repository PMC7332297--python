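"""Synthetic environments: random cube mazes, bond-percolation lattices, toy traps.

Everything downstream (geometry, trap statistics, simulators) consumes the
two environment types defined here.  A cube maze emulates the experimental
arena: a 70 x 50 cm board over which square obstacles of 0.8 cm edge are
spread uniformly at random without overlap, traversed by a disc-shaped load
of radius 1.1 cm starting at the mid-height of the left edge and biased
toward the open right ("nest") edge.  A bond lattice is a rectangular grid
whose edges are independently open with probability ``p``.

All generators are deterministic for a fixed seed.  Ensembles derive one
PRNG stream per maze from ``(master seed, maze index)`` so that generation
order never matters.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BoardSpec",
    "MazeConfig",
    "BondLattice",
    "generate_cube_maze",
    "generate_bond_lattice",
    "generate_maze_ensemble",
    "make_toy_trap",
    "cube_corners",
    "maze_to_json",
    "maze_from_json",
    "maze_to_csv",
    "maze_from_csv",
    "save_lattice",
    "load_lattice",
]

#: hard cap on rejection-sampling attempts for one maze
_MAX_ATTEMPTS = 1_000_000


class PlacementInfeasibleError(RuntimeError):
    """Raised when non-overlapping cube placement cannot be completed."""


@dataclass(frozen=True)
class BoardSpec:
    """Arena dimensions and the two length scales of the transport problem.

    Parameters
    ----------
    width, height : float
        Board extent in cm.  The load starts at ``(0, height/2)`` and the
        nest edge is ``x = width``; the other three edges are walls.
    cube_edge : float
        Edge length ``a`` of the square obstacles, cm.
    load_radius : float
        Radius ``R`` of the disc load, cm.  Configuration space is the
        board minus the obstacles dilated by a disc of this radius.
    """

    width: float = 70.0
    height: float = 50.0
    cube_edge: float = 0.8
    load_radius: float = 1.1

    def __post_init__(self) -> None:
        for name in ("width", "height", "cube_edge", "load_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.load_radius >= min(self.width, self.height) / 2:
            raise ValueError("load_radius must be < min(width, height)/2")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class MazeConfig:
    """A continuous cube maze: board plus obstacle poses.

    ``cubes`` is a sequence of ``(center_x, center_y, rotation)`` triples in
    cm / radians.  Footprints must lie fully inside the board and may touch
    but never overlap.
    """

    board: BoardSpec
    cubes: tuple[tuple[float, float, float], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cubes", tuple(tuple(map(float, c)) for c in self.cubes))

    @property
    def n_cubes(self) -> int:
        return len(self.cubes)

    def cube_corner_array(self) -> np.ndarray:
        """World-frame corners of every cube, shape ``(n, 4, 2)``."""
        return cube_corners(np.asarray(self.cubes, float).reshape(-1, 3), self.board.cube_edge)

    def validate(self) -> None:
        """Check the containment and pairwise non-overlap invariants."""
        if not self.cubes:
            return
        corners = self.cube_corner_array()
        lo = corners.min(axis=1)
        hi = corners.max(axis=1)
        tol = 1e-9
        if (lo < -tol).any() or (hi[:, 0] > self.board.width + tol).any() or (
            hi[:, 1] > self.board.height + tol
        ).any():
            raise ValueError("cube footprint extends outside the board")
        arr = np.asarray(self.cubes, float)
        a = self.board.cube_edge
        n = len(arr)
        # only test pairs closer than the diameter of a square's circumcircle
        reach = a * math.sqrt(2.0)
        for i in range(n):
            d = np.hypot(arr[i + 1 :, 0] - arr[i, 0], arr[i + 1 :, 1] - arr[i, 1])
            for j in np.nonzero(d < reach)[0] + i + 1:
                if _squares_overlap(arr[i], arr[j], a):
                    raise ValueError(f"cubes {i} and {j} overlap")


@dataclass(frozen=True)
class BondLattice:
    """Rectangular grid with independently open/closed edges.

    Nodes are indexed ``(row, col)`` with ``ny`` rows and ``nx`` columns.
    ``horizontal_edges[r, c]`` joins ``(r, c)`` and ``(r, c+1)``;
    ``vertical_edges[r, c]`` joins ``(r, c)`` and ``(r+1, c)``.
    """

    nx: int
    ny: int
    horizontal_edges: np.ndarray = field(repr=False)
    vertical_edges: np.ndarray = field(repr=False)
    p: float
    seed: int | None = None

    def __post_init__(self) -> None:
        h, v = self.horizontal_edges, self.vertical_edges
        if h.shape != (self.ny, self.nx - 1) or v.shape != (self.ny - 1, self.nx):
            raise ValueError("edge mask shapes inconsistent with (nx, ny)")
        n_edges = h.size + v.size
        if n_edges and 0.0 < self.p < 1.0:
            frac = (h.sum() + v.sum()) / n_edges
            sd = math.sqrt(self.p * (1 - self.p) / n_edges)
            if abs(frac - self.p) > 5 * sd:
                raise ValueError("empirical open fraction is >5 sd away from p")

    @property
    def open_fraction(self) -> float:
        n = self.horizontal_edges.size + self.vertical_edges.size
        return float(self.horizontal_edges.sum() + self.vertical_edges.sum()) / n


# ---------------------------------------------------------------------------
# geometry helpers


def cube_corners(cubes: np.ndarray, edge: float) -> np.ndarray:
    """Corners of rotated squares, ``cubes`` rows are (x, y, angle)."""
    cubes = np.asarray(cubes, float).reshape(-1, 3)
    half = edge / 2.0
    base = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    c, s = np.cos(cubes[:, 2]), np.sin(cubes[:, 2])
    rot = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)  # (n,2,2)
    return cubes[:, None, :2] + np.einsum("nij,kj->nki", rot, base)


def _squares_overlap(c1: np.ndarray, c2: np.ndarray, edge: float) -> bool:
    """Positive-area intersection test for two rotated squares (SAT).

    Touching squares (zero-area contact) count as non-overlapping.
    """
    half = edge / 2.0
    dx, dy = c2[0] - c1[0], c2[1] - c1[1]
    for theta in (c1[2], c2[2]):
        co, si = math.cos(theta), math.sin(theta)
        for ax, ay in ((co, si), (-si, co)):
            # half-extent of a rotated square projected on (ax, ay)
            e1 = half * (abs(ax * math.cos(c1[2]) + ay * math.sin(c1[2]))
                         + abs(-ax * math.sin(c1[2]) + ay * math.cos(c1[2])))
            e2 = half * (abs(ax * math.cos(c2[2]) + ay * math.sin(c2[2]))
                         + abs(-ax * math.sin(c2[2]) + ay * math.cos(c2[2])))
            if abs(ax * dx + ay * dy) >= e1 + e2 - 1e-12:
                return False
    return True


# ---------------------------------------------------------------------------
# generators


def generate_cube_maze(
    n_cubes: int,
    board: BoardSpec | None = None,
    seed: int | None = 0,
    axis_aligned: bool = False,
) -> MazeConfig:
    """Spread ``n_cubes`` non-overlapping squares uniformly over the board.

    Placement is by rejection sampling: a rotation is drawn uniformly on
    ``[0, pi/2)`` (square symmetry), the center uniformly over all positions
    keeping the footprint inside the board, and the cube is accepted if its
    footprint overlaps no previously placed cube (tangency is allowed).

    Raises
    ------
    PlacementInfeasibleError
        If one million attempts do not suffice (extreme densities).
    """
    board = board or BoardSpec()
    if n_cubes < 0:
        raise ValueError("n_cubes must be >= 0")
    rng = np.random.default_rng(seed)
    a = board.cube_edge
    placed = np.empty((n_cubes, 3))
    # coarse spatial hash for candidate neighbours
    cell = a * math.sqrt(2.0)
    nx_b = max(1, int(board.width / cell))
    ny_b = max(1, int(board.height / cell))
    buckets: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    k = 0
    while k < n_cubes:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise PlacementInfeasibleError(
                f"placed {k}/{n_cubes} cubes after {_MAX_ATTEMPTS} attempts"
            )
        theta = 0.0 if axis_aligned else rng.uniform(0.0, math.pi / 2.0)
        # footprint half-extent along each board axis for this rotation
        sx = (a / 2.0) * (abs(math.cos(theta)) + abs(math.sin(theta)))
        x = rng.uniform(sx, board.width - sx)
        y = rng.uniform(sx, board.height - sx)
        cand = np.array([x, y, theta])
        bi = min(int(x / board.width * nx_b), nx_b - 1)
        bj = min(int(y / board.height * ny_b), ny_b - 1)
        ok = True
        for ii in range(bi - 1, bi + 2):
            for jj in range(bj - 1, bj + 2):
                for idx in buckets.get((ii, jj), ()):
                    if _squares_overlap(placed[idx], cand, a):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            placed[k] = cand
            buckets.setdefault((bi, bj), []).append(k)
            k += 1
    return MazeConfig(board=board, cubes=tuple(map(tuple, placed[:n_cubes])), seed=seed)


def generate_maze_ensemble(
    n_cubes: int,
    n_mazes: int,
    board: BoardSpec | None = None,
    seed: int = 0,
    axis_aligned: bool = False,
) -> list[MazeConfig]:
    """Independent mazes with per-maze streams keyed by (seed, index)."""
    return [
        generate_cube_maze(
            n_cubes, board,
            seed=int(np.random.SeedSequence((seed, i)).generate_state(1)[0]),
            axis_aligned=axis_aligned,
        )
        for i in range(n_mazes)
    ]


def generate_bond_lattice(
    nx: int, ny: int, p: float, seed: int | None = 0
) -> BondLattice:
    """Rectangular lattice with each edge independently open w.p. ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    h = rng.random((ny, nx - 1)) < p
    v = rng.random((ny - 1, nx)) < p
    return BondLattice(nx=nx, ny=ny, horizontal_edges=h, vertical_edges=v, p=p, seed=seed)


# ---------------------------------------------------------------------------
# deterministic toy-trap fixtures (axis-aligned cubes)

# measured escape depth of the cup fixture is close to 2*arm_length + _CUP_D0
# for the default interior width; the constant absorbs the fixed lateral
# detour around one arm (see trap_analysis.trap_depth)
_CUP_D0 = 2.65
_CUP_INNER_WIDTH = 4.0


def make_toy_trap(
    kind: str, depth_hint: float = 6.0, board: BoardSpec | None = None
) -> MazeConfig:
    """Deterministic composite-obstacle fixtures centred at mid-height.

    ``single_cube`` is one axis-aligned cube at the board centre; ``cup`` is
    a U-shaped arrangement opening toward the start (-x) side whose measured
    trap depth is close to ``depth_hint``; ``wedge`` is a V with its apex
    pointing toward the nest (+x).
    """
    board = board or BoardSpec()
    a = board.cube_edge
    xc, yc = board.width / 2.0, board.height / 2.0
    pitch = 1.0  # cube-centre spacing; gap 0.2 cm < 2R so dilations merge
    cubes: list[tuple[float, float, float]] = []
    if kind == "single_cube":
        cubes.append((xc, yc, 0.0))
    elif kind == "cup":
        arm = max(0.0, (depth_hint - _CUP_D0) / 2.0)
        n_arm = max(1, int(round(arm / pitch)) + 1)
        w = _CUP_INNER_WIDTH + a  # centre-to-centre distance between arms
        x_back = xc + (n_arm - 1) * pitch / 2.0
        # back wall
        n_wall = int(round(w / pitch)) + 1
        for j in range(n_wall):
            cubes.append((x_back, yc - w / 2.0 + j * pitch, 0.0))
        # arms extending toward -x
        for i in range(1, n_arm):
            cubes.append((x_back - i * pitch, yc - w / 2.0, 0.0))
            cubes.append((x_back - i * pitch, yc + w / 2.0, 0.0))
    elif kind == "wedge":
        n_side = max(2, int(round(depth_hint / pitch)))
        step = 0.85  # per-axis offset > cube edge so axis-aligned footprints clear

        apex = (xc + depth_hint / 2.0, yc)
        cubes.append((apex[0], apex[1], 0.0))
        for i in range(1, n_side + 1):
            cubes.append((apex[0] - i * step, yc + i * step, 0.0))
            cubes.append((apex[0] - i * step, yc - i * step, 0.0))
    else:
        raise ValueError(f"unknown toy trap kind: {kind!r}")
    maze = MazeConfig(board=board, cubes=tuple(cubes), seed=None)
    maze.validate()
    return maze


# ---------------------------------------------------------------------------
# file formats
#
# Maze JSON: {"board": {...}, "cubes": [[x, y, angle], ...]} with units
# cm/radians, origin at the start corner (x grows toward the nest edge).
# Cube CSV: one cube per row (x, y, angle) with a header, for interchange
# with deposited cube-coordinate tables.


def maze_to_json(maze: MazeConfig, path: str | Path) -> None:
    payload = {
        "board": {
            "width": maze.board.width,
            "height": maze.board.height,
            "cube_edge": maze.board.cube_edge,
            "load_radius": maze.board.load_radius,
        },
        "seed": maze.seed if isinstance(maze.seed, (int, type(None))) else None,
        "cubes": [list(c) for c in maze.cubes],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def maze_from_json(path: str | Path) -> MazeConfig:
    payload = json.loads(Path(path).read_text())
    board = BoardSpec(**payload["board"])
    return MazeConfig(board=board, cubes=tuple(map(tuple, payload["cubes"])),
                      seed=payload.get("seed"))


def maze_to_csv(maze: MazeConfig, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_cm", "y_cm", "angle_rad"])
        writer.writerows(maze.cubes)


def maze_from_csv(path: str | Path, board: BoardSpec | None = None) -> MazeConfig:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    cubes = tuple((float(x), float(y), float(t)) for x, y, t in rows[1:])
    return MazeConfig(board=board or BoardSpec(), cubes=cubes)


def save_lattice(lattice: BondLattice, path: str | Path) -> None:
    np.savez_compressed(
        path,
        horizontal=lattice.horizontal_edges,
        vertical=lattice.vertical_edges,
        meta=np.array([lattice.nx, lattice.ny], dtype=np.int64),
        p=np.array(lattice.p),
        seed=np.array(-1 if lattice.seed is None else lattice.seed, dtype=np.int64),
    )


def load_lattice(path: str | Path) -> BondLattice:
    with np.load(path) as data:
        nx, ny = (int(v) for v in data["meta"])
        seed = int(data["seed"])
        return BondLattice(
            nx=nx, ny=ny,
            horizontal_edges=data["horizontal"], vertical_edges=data["vertical"],
            p=float(data["p"]), seed=None if seed < 0 else seed,
        )
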