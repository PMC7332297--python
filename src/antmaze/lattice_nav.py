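"""Discrete navigation experiments on bond-percolation lattices.

The continuous cube-maze problem has a classical discrete counterpart:
a walker on the giant component of a square lattice whose edges are open
independently with probability ``p`` (just above the bond-percolation
threshold 1/2), biased toward the far side.  This module implements

* giant-component extraction and left-right spanning tests,
* the biased random walker (``p_right = 0.25 + B``) and its drift speed,
  including the bias sweep that locates the drift-maximizing ``B``,
* the logarithmic extended-vision bout algorithm: repeated shortest-path
  bouts inside a window of radius ``gamma * log2(N)``, each ending on a
  strip column ``gamma * log2(N)`` ahead,
* unconstrained (``D``) and strip-constrained (``D_tilde``) shortest
  paths between the internal strip's end columns, and
* the traversal-speedup comparison between the two strategies.

Lattice dimensions follow the ``N x delta*log2(N)`` construction with a
concentric internal strip of width ``alpha * log2(N)``; log base 2 is
used throughout.  Full-scale runs (N = 70000) work but take hours; the
default experiments use reduced N with the same scaling formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _lattice_kernels as lk
from .synthetic_env import BondLattice, generate_bond_lattice

__all__ = [
    "StripSpec",
    "VisionParams",
    "LatticeRWParams",
    "PathPair",
    "UnreachableTerminalError",
    "scaled_lattice_shape",
    "giant_component",
    "spans_left_right",
    "start_node",
    "biased_rw_lattice",
    "extended_vision_walk",
    "shortest_paths",
    "speedup_experiment",
    "bond_threshold_estimate",
    "sensing_scale_ratio",
]


class UnreachableTerminalError(RuntimeError):
    """The bout walker could not reach the rightmost strip column."""


def scaled_lattice_shape(N: int, delta: float = 120.0) -> tuple[int, int]:
    """(nx, ny) of the standard construction: N columns by delta*log2(N) rows."""
    return N, int(round(delta * math.log2(N)))


@dataclass(frozen=True)
class StripSpec:
    """The internal strip: a concentric band of rows of logarithmic width.

    ``row_lo:row_hi`` is the half-open row band.  ``alpha`` and ``delta``
    record the construction constants (strip width ``alpha * log2(N)``
    inside a lattice of height ``delta * log2(N)``).
    """

    nx: int
    ny: int
    row_lo: int
    row_hi: int
    alpha: float = 20.0
    delta: float = 120.0

    def __post_init__(self) -> None:
        if not (0 <= self.row_lo < self.row_hi <= self.ny):
            raise ValueError("strip must fit inside the lattice")

    @property
    def width(self) -> int:
        return self.row_hi - self.row_lo

    @property
    def center_row(self) -> int:
        return (self.row_lo + self.row_hi) // 2

    @property
    def span(self) -> int:
        """Aerial distance d between the strip's end columns, in edges."""
        return self.nx - 1

    @classmethod
    def for_lattice(
        cls, lattice: BondLattice, alpha: float = 20.0, delta: float = 120.0
    ) -> "StripSpec":
        width = int(round(alpha * math.log2(lattice.nx)))
        width = min(width, lattice.ny)
        center = lattice.ny // 2
        lo = max(0, center - width // 2)
        return cls(nx=lattice.nx, ny=lattice.ny, row_lo=lo, row_hi=lo + width,
                   alpha=alpha, delta=delta)


@dataclass(frozen=True)
class VisionParams:
    """Sensing geometry of the bout walker.

    The vision radius and per-bout goal advance are both
    ``gamma * log2(N)``, which also equals the strip width when
    ``gamma = alpha`` (the construction used throughout).
    """

    gamma: float = 20.0

    def radius(self, N: int) -> int:
        return int(round(self.gamma * math.log2(N)))


@dataclass(frozen=True)
class LatticeRWParams:
    """Bias and step cap of the lattice random walker."""

    B: float = 0.045
    max_steps: int = 150_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.B <= 0.75:
            raise ValueError("B must be in [0, 0.75]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class PathPair:
    """Unconstrained vs strip-constrained shortest-path lengths (edges)."""

    D: float
    D_tilde: float
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.feasible and self.D_tilde < self.D:
            raise ValueError("strip-constrained path cannot beat the free one")

    @property
    def ratio_excess(self) -> float:
        return self.D_tilde / self.D - 1.0


# ---------------------------------------------------------------------------


def giant_component(lattice: BondLattice) -> np.ndarray:
    """Boolean mask of the largest connected component of the open graph."""
    labels, sizes = lk.label_components(
        np.ascontiguousarray(lattice.horizontal_edges),
        np.ascontiguousarray(lattice.vertical_edges),
    )
    return labels == int(np.argmax(sizes))


def spans_left_right(lattice: BondLattice) -> bool:
    """True iff one open cluster touches both the first and last column."""
    labels, _ = lk.label_components(
        np.ascontiguousarray(lattice.horizontal_edges),
        np.ascontiguousarray(lattice.vertical_edges),
    )
    # single-node components span only a 1-column lattice
    if lattice.nx == 1:
        return True
    left = np.unique(labels[:, 0])
    right = np.unique(labels[:, -1])
    common = np.intersect1d(left, right, assume_unique=True)
    if common.size == 0:
        return False
    sizes = np.bincount(labels.ravel())
    return bool((sizes[common] > 1).any())


def start_node(lattice: BondLattice, strip: StripSpec,
               giant: np.ndarray | None = None) -> tuple[int, int]:
    """Giant-component node closest to the strip's leftmost-column center.

    Ties break toward the smaller row index; deterministic.
    """
    if giant is None:
        giant = giant_component(lattice)
    if not giant.any():
        raise RuntimeError("giant component is empty")
    rc = strip.center_row
    best = None
    best_d2 = np.inf
    for c in range(lattice.nx):
        if c * c > best_d2:
            break
        rows = np.nonzero(giant[:, c])[0]
        if rows.size == 0:
            continue
        d2 = (rows - rc).astype(np.int64) ** 2 + c * c
        i = int(np.argmin(d2))  # argmin returns the first (smallest row) tie
        if d2[i] < best_d2:
            best_d2 = d2[i]
            best = (int(rows[i]), c)
    if best is None:
        raise RuntimeError("giant component is empty")
    return best


def biased_rw_lattice(
    lattice: BondLattice,
    params: LatticeRWParams | None = None,
    seed: int = 0,
    strip: StripSpec | None = None,
    giant: np.ndarray | None = None,
) -> tuple[dict, float]:
    """One capped biased walk from the strip's start node.

    Returns ``(record, drift_speed)`` where drift speed is the net column
    advance per step over the (possibly capped) walk — the speed measure
    used when walks do not terminate within the cap.
    """
    params = params or LatticeRWParams()
    strip = strip or StripSpec.for_lattice(lattice)
    r0, c0 = start_node(lattice, strip, giant)
    net, steps, reached, r, c = lk.biased_walk(
        np.ascontiguousarray(lattice.horizontal_edges),
        np.ascontiguousarray(lattice.vertical_edges),
        r0, c0, float(params.B), int(params.max_steps), lattice.nx - 1,
        int(seed) % (2**31),
    )
    record = {
        "start": (r0, c0),
        "end": (int(r), int(c)),
        "net_cols": int(net),
        "steps": int(steps),
        "reached": bool(reached),
        "B": params.B,
        "seed": seed,
    }
    return record, net / steps if steps else 0.0


def shortest_paths(lattice: BondLattice, strip: StripSpec | None = None) -> PathPair:
    """Shortest left-to-right strip crossings, free and strip-constrained.

    Both paths run from the strip rows of the first column to the strip
    rows of the last column; ``D`` may use any lattice node while
    ``D_tilde`` is confined to the strip band.  Disconnected instances
    are returned with ``feasible=False``.
    """
    strip = strip or StripSpec.for_lattice(lattice)
    h = np.ascontiguousarray(lattice.horizontal_edges)
    v = np.ascontiguousarray(lattice.vertical_edges)
    rows = np.arange(strip.row_lo, strip.row_hi, dtype=np.int64)
    cols0 = np.zeros(len(rows), dtype=np.int64)
    vals = []
    for constrained in (False, True):
        lo, hi = (strip.row_lo, strip.row_hi) if constrained else (0, 0)
        dist = lk.bfs_distances(
            h, v, rows, cols0, 0, lattice.ny, 0, lattice.nx, lo, hi
        )
        d_last = dist[strip.row_lo : strip.row_hi, -1]
        d_last = d_last[d_last >= 0]
        vals.append(int(d_last.min()) if d_last.size else -1)
    free, within = vals
    return PathPair(
        D=float(free) if free >= 0 else math.inf,
        D_tilde=float(within) if within >= 0 else math.inf,
        feasible=free >= 0 and within >= 0,
    )


def extended_vision_walk(
    lattice: BondLattice,
    strip: StripSpec | None = None,
    vision: VisionParams | None = None,
    giant: np.ndarray | None = None,
) -> int:
    """Total path length (steps) of the logarithmic-window bout walker.

    Each bout runs a shortest path inside the vision square to any
    giant-component node of the strip column ``radius`` ahead (clamped to
    the last column).  If no goal-column node is reachable within the
    window, the walker instead targets the reachable strip node with the
    greatest column advance; if nothing advances, the window is enlarged
    once by 2x before giving up.
    """
    strip = strip or StripSpec.for_lattice(lattice)
    vision = vision or VisionParams()
    if giant is None:
        giant = giant_component(lattice)
    h = np.ascontiguousarray(lattice.horizontal_edges)
    v = np.ascontiguousarray(lattice.vertical_edges)
    radius = vision.radius(lattice.nx)
    r, c = start_node(lattice, strip, giant)
    total = 0
    last_col = lattice.nx - 1
    while c < last_col:
        step = _one_bout(lattice, strip, giant, h, v, r, c, radius, last_col)
        if step is None:
            step = _one_bout(lattice, strip, giant, h, v, r, c, 2 * radius, last_col)
        if step is None:
            raise UnreachableTerminalError(
                f"bout walker stalled at node ({r}, {c})"
            )
        d, r, c = step
        total += d
    return total


def _one_bout(lattice, strip, giant, h, v, r, c, radius, last_col):
    goal_col = min(c + radius, last_col)
    r_lo = max(0, r - radius)
    r_hi = min(lattice.ny, r + radius + 1)
    c_lo = max(0, c - radius)
    c_hi = min(lattice.nx, c + radius + 1)
    if goal_col >= c_hi:  # window must contain its goal column
        c_hi = goal_col + 1
    dist = lk.bfs_distances(
        h, v,
        np.array([r], dtype=np.int64), np.array([c], dtype=np.int64),
        r_lo, r_hi, c_lo, c_hi, 0, 0,
    )
    srows = np.arange(max(strip.row_lo, r_lo), min(strip.row_hi, r_hi))
    if srows.size == 0:
        return None
    goal_d = dist[srows - r_lo, goal_col - c_lo]
    ok = (goal_d >= 0) & giant[srows, goal_col]
    if ok.any():
        i = int(np.argmin(np.where(ok, goal_d, np.iinfo(np.int32).max)))
        return int(goal_d[i]), int(srows[i]), goal_col
    # fallback: best column advance among reachable strip nodes in window
    sub = dist[srows - r_lo, :]
    reach = (sub >= 0) & giant[srows, c_lo:c_hi]
    cols = np.nonzero(reach.any(axis=0))[0]
    cols = cols[cols + c_lo > c]
    if cols.size == 0:
        return None
    best_c = int(cols.max())
    rows_ok = np.nonzero(reach[:, best_c])[0]
    d_at = sub[rows_ok, best_c]
    j = int(np.argmin(d_at))
    return int(d_at[j]), int(srows[rows_ok[j]]), best_c + c_lo


def speedup_experiment(
    lattices: list[BondLattice],
    b_grid: np.ndarray | list[float] | None = None,
    vision: VisionParams | None = None,
    max_steps: int = 150_000,
    seed: int = 0,
    walks_per_lattice: int = 1,
) -> dict:
    """Traversal-time speedup of extended vision over the best biased walk.

    For every lattice and bias the capped-walk drift speed (columns per
    step) is measured; the drift-maximizing bias on the grid is selected
    by the mean over lattices, the biased crossing time extrapolated as
    ``d / drift``, and compared with the bout walker's path length (its
    time in unit steps).  Returns the per-lattice speedups along with the
    drift table.
    """
    if len(lattices) < 1:
        raise ValueError("need at least one lattice")
    b_grid = np.asarray(
        b_grid if b_grid is not None
        else [0.01, 0.02, 0.03, 0.045, 0.06, 0.08, 0.10, 0.125, 0.15]
    )
    vision = vision or VisionParams()
    drifts = np.zeros((len(lattices), len(b_grid)))
    vision_lengths = np.zeros(len(lattices))
    for i, lat in enumerate(lattices):
        strip = StripSpec.for_lattice(lat)
        giant = giant_component(lat)
        for j, B in enumerate(b_grid):
            vals = []
            for w in range(walks_per_lattice):
                sub = int(np.random.SeedSequence((seed, i, j, w)).generate_state(1)[0])
                _, v_drift = biased_rw_lattice(
                    lat, LatticeRWParams(B=float(B), max_steps=max_steps),
                    seed=sub, strip=strip, giant=giant,
                )
                vals.append(v_drift)
            drifts[i, j] = np.mean(vals)
        vision_lengths[i] = extended_vision_walk(lat, strip, vision, giant)
    best_j = int(np.argmax(drifts.mean(axis=0)))
    d = lattices[0].nx - 1
    best_drift = drifts[:, best_j]
    with np.errstate(divide="ignore"):
        crossing_time = np.where(best_drift > 0, d / best_drift, np.inf)
    speedups = crossing_time / vision_lengths
    return {
        "b_grid": b_grid,
        "drifts": drifts,
        "best_B": float(b_grid[best_j]),
        "vision_lengths": vision_lengths,
        "speedups": speedups,
        "mean_speedup": float(np.mean(speedups[np.isfinite(speedups)])),
        "std_speedup": float(np.std(speedups[np.isfinite(speedups)])),
    }


def bond_threshold_estimate(
    size: int = 200,
    p_grid: np.ndarray | list[float] | None = None,
    reps: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Spanning-probability sweep and its 0.5 crossing on square lattices.

    For each ``p`` the probability that an open cluster spans left to
    right is estimated over ``reps`` seeded ``size x size`` lattices; the
    threshold is where a monotone fit of that probability crosses 0.5
    (exactly 1/2 for bond percolation on the square lattice in the
    infinite-size limit).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p_grid = np.asarray(p_grid if p_grid is not None else np.arange(0.40, 0.605, 0.01))
    rows = []
    for p in p_grid:
        hits = 0
        for rep in range(reps):
            sub = int(
                np.random.SeedSequence((seed, int(round(p * 1000)), rep))
                .generate_state(1)[0]
            )
            lat = generate_bond_lattice(size, size, float(p), seed=sub)
            hits += spans_left_right(lat)
        rows.append({"p": float(p), "spanning_probability": hits / reps})
    table = pd.DataFrame(rows)
    threshold = _crossing_increasing(
        table["p"].to_numpy(), table["spanning_probability"].to_numpy()
    )
    return table, threshold


def _crossing_increasing(x: np.ndarray, y: np.ndarray, level: float = 0.5) -> float:
    from sklearn.isotonic import IsotonicRegression

    fit = IsotonicRegression(increasing=True).fit(x, y).predict(x)
    for i in range(len(x) - 1):
        if fit[i] <= level <= fit[i + 1]:
            if fit[i + 1] == fit[i]:
                return float((x[i] + x[i + 1]) / 2)
            t = (level - fit[i]) / (fit[i + 1] - fit[i])
            return float(x[i] + t * (x[i + 1] - x[i]))
    return float(x[np.argmin(np.abs(fit - level))])


def sensing_scale_ratio(n_large: float = 1000.0, n_small: float = 70.0) -> float:
    """Ratio of optimal sensing ranges for two system sizes, log(n1)/log(n2).

    Because optimal sensing range grows logarithmically with system size,
    scaling a habitat from a 70 cm arena to a 10 m foraging range (1000
    grid units) changes the appropriate sensing range by only
    log(1000)/log(70) ~ 1.6 -- the base of the logarithm cancels.
    """
    return math.log(n_large) / math.log(n_small)
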