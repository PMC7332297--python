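"""Responsive transport models: stuck detection, the non-local
bias-direction field, and the extended-sensing pinball simulator.

A carried load that stops advancing is "stuck".  Responsive models react
to that event; they differ in what information the reaction uses:

* local variants either temporarily rescale the force noise or draw a
  uniformly random temporary bias direction — no environmental input;
* the extended-sensing model redirects its bias along a precomputed
  direction field that encodes the local trap structure out to a sensing
  radius ``r_sense`` — a stand-in for the information carried to the
  group by scout ants exploring up to ~10 cm from the load.

The field is evaluated on a 0.5 cm grid.  For each cell center the
algorithm (i) snaps centers inside an obstacle blob to the blob boundary
and drops fully interior cells, (ii) drops cells with no blob within
0.25 cm directly ahead (+x) — such cells cannot host a stuck load,
(iii) finds the nearest boundary point ("seed") of the blocking blob,
(iv) walks ``r_sense`` cm along the boundary in both directions,
(v) takes each walked piece's minimum-x point, (vi) forms the seed-to-
point directions rotated 15 degrees away from the blob interior, and
(vii) keeps whichever direction points more toward the nest.  A short
sensing range leaves both candidate points inside a deep trap and the
chosen direction points backward — exactly the degradation that makes
small ``r_sense`` ineffective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .maze_geometry import AccessGrid, access_grid
from .pinball import PinballParams, _cube_tables, _find_free_start, _EMPTY_FIELD
from .synthetic_env import MazeConfig
from .trajectory import Trajectory
from .trap_analysis import label_blobs

__all__ = [
    "ResponsiveParams",
    "WalkerMode",
    "BiasField",
    "detect_stuck",
    "compute_bias_field",
    "simulate_extended_pinball",
    "simulate_local_responsive",
]

#: bias-field grid pitch, cm
FIELD_PITCH = 0.5
#: forward ray of the blocked-cell test, cm (shared with trap_analysis)
BLOCK_RAY_LENGTH = 0.25
#: rotation applied to boundary-point directions, radians
ROTATE_AWAY = math.radians(15.0)


@dataclass(frozen=True)
class ResponsiveParams:
    """Stuck-detection state machine and sensing parameters.

    The load is stuck when it advanced less than ``dx_min`` over the last
    ``t_compare`` seconds; it then keeps an altered state for
    ``t_changed`` seconds and is immune to re-detection for ``t_cooldown``
    more.  ``noise_correlation_time`` block-holds the noise vector, giving
    the persistent kicks needed to actually follow an escape direction.
    """

    dx_min: float = 0.2  # cm
    t_compare: float = 3.0  # s
    t_changed: float = 4.48  # s
    t_cooldown: float = 4.0  # s
    r_sense: float = 10.0  # cm
    noise_correlation_time: float = 0.4  # s
    stuck_sigma: float = -1.0  # noise amplitude while escaping; < 0 keeps sigma_f
    correlate_free: bool = True  # hold noise blocks in the free state too
    follow_field: bool = False  # track the field while stuck (re-acquire per block)

    def __post_init__(self) -> None:
        for name in ("dx_min", "t_compare", "t_changed", "t_cooldown",
                     "r_sense", "noise_correlation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stuck_sigma >= 0 and not np.isfinite(self.stuck_sigma):
            raise ValueError("stuck_sigma must be finite")

    def steps(self, dt: float) -> tuple[int, int, int, int]:
        """(compare, changed, cooldown, noise-block) windows in steps."""
        n_cmp = round(self.t_compare / dt)
        if abs(n_cmp * dt - self.t_compare) > 1e-9:
            raise ValueError("t_compare must be a multiple of the timestep")
        return (
            n_cmp,
            max(1, round(self.t_changed / dt)),
            max(1, round(self.t_cooldown / dt)),
            max(1, round(self.noise_correlation_time / dt)),
        )


@dataclass(frozen=True)
class WalkerMode:
    """Snapshot of the state machine (used by trace audits)."""

    mode: str  # "free" | "stuck" | "cooldown"
    mode_entry_time: float
    active_bias_direction: tuple[float, float]


@dataclass(frozen=True)
class BiasField:
    """Precomputed escape-direction field on a 0.5 cm grid.

    ``defined`` marks cells passing the algorithm's filters; ``dx, dy``
    hold the unit escape direction there.  Deterministic for a fixed maze
    and sensing radius.
    """

    pitch: float
    defined: np.ndarray = field(repr=False)
    dx: np.ndarray = field(repr=False)
    dy: np.ndarray = field(repr=False)
    r_sense: float = 10.0

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "dx", "dy"])
            for i, j in np.argwhere(self.defined):
                writer.writerow(
                    [(j + 0.5) * self.pitch, (i + 0.5) * self.pitch,
                     self.dx[i, j], self.dy[i, j]]
                )


def detect_stuck(
    recent_x: np.ndarray, params: ResponsiveParams, dt: float = 0.04
) -> bool:
    """True iff net x advance over a full ``t_compare`` window < ``dx_min``.

    ``recent_x`` must hold ``t_compare/dt + 1`` samples (the window's two
    endpoints inclusive).  The comparison is on the absolute net motion
    (a load kicked backward has moved, and is not stalled) and strict:
    advancing exactly ``dx_min`` is not stuck.
    """
    recent_x = np.asarray(recent_x, float)
    n_expected = round(params.t_compare / dt) + 1
    if len(recent_x) != n_expected:
        raise ValueError(
            f"window must span exactly t_compare: need {n_expected} samples, "
            f"got {len(recent_x)}"
        )
    return bool(abs(recent_x[-1] - recent_x[0]) < params.dx_min)


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def compute_bias_field(
    maze: MazeConfig,
    grid: AccessGrid | None = None,
    r_sense: float = 10.0,
) -> BiasField:
    """Evaluate the escape-direction field of a maze (see module docstring)."""
    grid = grid if grid is not None else access_grid(maze)
    board = maze.board
    h = grid.cell_size
    labels, blobs = label_blobs(maze, grid)
    by_label = {b.label: b for b in blobs}
    contour_trees = {}
    cell_trees = {}
    cum_arcs = {}
    for b in blobs:
        if len(b.boundary) < 2:
            continue
        contour_trees[b.label] = cKDTree(b.boundary)
        cells_cm = np.column_stack(
            [grid.x_of_col(b.cells[:, 1]), grid.y_of_row(b.cells[:, 0])]
        )
        cell_trees[b.label] = cKDTree(cells_cm)
        seg = np.diff(b.boundary, axis=0)
        cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        cum_arcs[b.label] = cum

    nxf = int(math.ceil(board.width / FIELD_PITCH))
    nyf = int(math.ceil(board.height / FIELD_PITCH))
    defined = np.zeros((nyf, nxf), dtype=np.uint8)
    fdx = np.zeros((nyf, nxf))
    fdy = np.zeros((nyf, nxf))
    ny, nx = grid.shape

    def label_at(x: float, y: float) -> int:
        col = int(x / h)
        row = int(y / h)
        if 0 <= row < ny and 0 <= col < nx:
            return int(labels[row, col])
        return 0

    # fine sampling of the forward ray, endpoint included
    ray_offsets = np.arange(0.05, BLOCK_RAY_LENGTH + 1e-9, 0.05)
    corner_off = FIELD_PITCH / 2.0
    for i in range(nyf):
        cy = (i + 0.5) * FIELD_PITCH
        for j in range(nxf):
            cx = (j + 0.5) * FIELD_PITCH
            p = np.array([cx, cy])
            lab_here = label_at(cx, cy)
            if lab_here > 0:
                # fully interior square: drop
                samples = [
                    (cx + sx, cy + sy)
                    for sx in (-corner_off, 0.0, corner_off)
                    for sy in (-corner_off, 0.0, corner_off)
                ]
                if all(label_at(sx, sy) == lab_here for sx, sy in samples):
                    continue
                if lab_here not in contour_trees:
                    continue
                _, idx = contour_trees[lab_here].query(p)
                p = by_label[lab_here].boundary[idx]
            # any blob directly ahead within the ray?
            lab_ahead = 0
            for off in ray_offsets:
                lab_ahead = label_at(p[0] + off, p[1])
                if lab_ahead > 0:
                    break
            if lab_ahead == 0 or lab_ahead not in contour_trees:
                continue
            blob = by_label[lab_ahead]
            boundary = blob.boundary
            cum = cum_arcs[lab_ahead]
            _, seed_idx = contour_trees[lab_ahead].query(p)
            seed = boundary[seed_idx]
            direction = _boundary_escape_direction(
                boundary, cum, seed_idx, r_sense, cell_trees[lab_ahead], seed
            )
            if direction is None:
                continue
            defined[i, j] = 1
            fdx[i, j] = direction[0]
            fdy[i, j] = direction[1]
    return BiasField(pitch=FIELD_PITCH, defined=defined, dx=fdx, dy=fdy,
                     r_sense=r_sense)


def _boundary_escape_direction(
    boundary: np.ndarray,
    cum: np.ndarray,
    seed_idx: int,
    r_sense: float,
    cell_tree: cKDTree,
    seed: np.ndarray,
) -> np.ndarray | None:
    """Steps (iv)-(vii): walk the boundary, pick min-x points, rotate, select."""
    total = cum[-1]
    n = len(boundary) - 1  # closed polyline: last vertex repeats the first
    if n < 2:
        return None
    # arc distance from the seed along each direction (closed curve)
    rel = cum - cum[seed_idx]
    fwd = np.where(rel >= 0, rel, rel + total)[:n]
    bwd = np.where(rel <= 0, -rel, total - rel)[:n]
    reach = min(r_sense, total / 2.0)
    piece_top = boundary[:n][fwd <= reach]
    piece_bot = boundary[:n][bwd <= reach]
    candidates = []
    # interior direction: toward the centroid of nearby blob cells
    near = cell_tree.query_ball_point(seed, 1.0)
    if near:
        interior = cell_tree.data[near].mean(axis=0) - seed
    else:
        interior = np.array([1.0, 0.0])
    for piece in (piece_top, piece_bot):
        if len(piece) == 0:
            continue
        pt = piece[np.argmin(piece[:, 0])]
        v = pt - seed
        norm = np.hypot(*v)
        if norm < 1e-9:
            continue
        v = v / norm
        plus, minus = _rotate(v, ROTATE_AWAY), _rotate(v, -ROTATE_AWAY)
        v = plus if plus @ interior < minus @ interior else minus
        candidates.append(v)
    if not candidates:
        return None
    best = max(candidates, key=lambda d: d[0])
    return best / np.hypot(*best)


def simulate_extended_pinball(
    maze: MazeConfig,
    pin: PinballParams | None = None,
    resp: ResponsiveParams | None = None,
    bias_field: BiasField | None = None,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    return_events: bool = False,
):
    """Pinball dynamics plus stuck-triggered non-local bias redirection.

    On a stuck event the bias direction becomes the field value at the
    nearest defined cell within 1.5 cm of the load (unchanged if none is
    defined nearby), reverts after ``t_changed`` and cannot re-trigger
    during ``t_cooldown``.  The model runs on time-correlated Brownian
    noise: the low-persistence amplitude (``sigma_f = 250``) held for
    ``noise_correlation_time`` blocks, which keeps the kicks comparable
    to the terminal speed so the redirected bias can actually be
    followed.  Correlated noise alone (no redirection) is the
    no-improvement control; redirection is what buys the performance.
    """
    pin = pin or PinballParams(sigma_f=250.0)
    resp = resp or ResponsiveParams()
    if bias_field is None:
        bias_field = compute_bias_field(maze, r_sense=resp.r_sense)
    if abs(bias_field.r_sense - resp.r_sense) > 1e-9:
        raise ValueError("bias field was computed with a different r_sense")
    n_cmp, n_chg, n_cool, n_noise = resp.steps(pin.dt)
    board = maze.board
    cubes, trig, cell_start, cell_items, ncx, ncy = _cube_tables(maze)
    x0, y0 = start or _find_free_start(maze)
    pos, n, solved, events, n_ev = _kernels.pinball_run(
        cubes, trig, cell_start, cell_items, ncx, ncy, 2.5,
        board.width, board.height, board.load_radius,
        pin.mass, pin.g_cm, pin.sigma_f_cm, pin.mu, pin.dt, pin.max_steps,
        float(x0), float(y0), int(seed) % (2**31),
        n_noise if resp.correlate_free else 1, pin.noise_folded, 0.0,
        _kernels.EXTENDED, 0.0,
        float(resp.stuck_sigma) * pin.unit_scale, n_noise,
        1 if resp.follow_field else 0,
        resp.dx_min, n_cmp, n_chg, n_cool,
        bias_field.defined, bias_field.dx, bias_field.dy, bias_field.pitch,
    )
    traj = Trajectory(
        times=np.arange(n + 1) * pin.dt,
        positions=pos,
        outcome="solved" if solved else "timed_out",
        seed=seed,
        model=f"extended_pinball(r={resp.r_sense:g})",
    )
    if return_events:
        return traj, events[:n_ev]
    return traj


_LOCAL_VARIANTS = {
    "altered_noise": _kernels.ALTERED_NOISE,
    "random_rebias": _kernels.RANDOM_REBIAS,
    "noise_scale": _kernels.PLAIN,
}


def simulate_local_responsive(
    maze: MazeConfig,
    pin: PinballParams | None = None,
    resp: ResponsiveParams | None = None,
    variant: str = "altered_noise",
    variant_param: float = 1.0,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    return_events: bool = False,
):
    """Local control models sharing the pinball engine and state machine.

    ``altered_noise`` multiplies the noise amplitude by ``variant_param``
    while stuck; ``random_rebias`` draws a uniformly random temporary bias
    direction; ``noise_scale`` is the non-responsive noise-level sweep
    (amplitude permanently scaled, no state machine).
    """
    pin = pin or PinballParams()
    resp = resp or ResponsiveParams()
    if variant not in _LOCAL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    board = maze.board
    cubes, trig, cell_start, cell_items, ncx, ncy = _cube_tables(maze)
    x0, y0 = start or _find_free_start(maze)
    if variant == "noise_scale":
        sigma = pin.sigma_f * variant_param
        n_cmp = n_chg = n_cool = 0
        n_noise = 1
    else:
        sigma = pin.sigma_f
        n_cmp, n_chg, n_cool, n_noise = resp.steps(pin.dt)
        n_noise = 1  # local variants keep per-step noise
    pos, n, solved, events, n_ev = _kernels.pinball_run(
        cubes, trig, cell_start, cell_items, ncx, ncy, 2.5,
        board.width, board.height, board.load_radius,
        pin.mass, pin.g_cm, sigma * pin.unit_scale, pin.mu, pin.dt, pin.max_steps,
        float(x0), float(y0), int(seed) % (2**31),
        n_noise, pin.noise_folded, 0.0,
        _LOCAL_VARIANTS[variant], float(variant_param),
        -1.0, 0, 0,
        resp.dx_min, n_cmp, n_chg, n_cool,
        *_EMPTY_FIELD,
    )
    traj = Trajectory(
        times=np.arange(n + 1) * pin.dt,
        positions=pos,
        outcome="solved" if solved else "timed_out",
        seed=seed,
        model=f"{variant}({variant_param:g})",
    )
    if return_events:
        return traj, events[:n_ev]
    return traj
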