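"""Cross-model benchmarking: success probabilities, penalty-adjusted arc
lengths, performance ratios and trajectory confinement.

Failed runs would otherwise report deceptively short arcs, so the arc
length of an unsuccessful crossing is penalized by the run's mean speed
times the time it spent stuck at the end — operationalized as the time
since the running maximum of ``x`` last improved.  Success estimates
carry binomial standard errors; arc lengths carry standard errors of the
mean.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .maze_geometry import access_grid, coverage
from .pinball import PinballParams, simulate_discrete_rw, simulate_pinball
from .responsive import (
    ResponsiveParams,
    compute_bias_field,
    simulate_extended_pinball,
    simulate_local_responsive,
)
from .synthetic_env import BoardSpec, generate_cube_maze
from .trajectory import Trajectory

__all__ = [
    "BenchmarkRecord",
    "penalty_adjusted_arc",
    "performance_ratio",
    "strip_confinement",
    "run_benchmark",
    "summarize",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One simulated crossing attempt, reduced to its benchmark metrics."""

    model: str
    maze_id: int
    coverage: float
    success: bool
    duration: float
    arc_length: float
    penalty_adjusted: float
    seed: int

    def __post_init__(self) -> None:
        if self.penalty_adjusted < self.arc_length - 1e-9:
            raise ValueError("penalty-adjusted arc cannot be below the arc length")


def penalty_adjusted_arc(traj: Trajectory, stuck_from: str = "last_progress") -> float:
    """Arc length with a failure penalty of mean speed x terminal stuck time.

    Successful runs are unchanged.  For failures, the stuck time runs
    from the last improvement of the running maximum of ``x`` (default)
    or, with ``stuck_from="last_max_entry"``, from the last time the
    trajectory was at its eventual maximum-x cell.
    """
    arc = traj.arc_length()
    if traj.outcome == "solved" or len(traj) < 2:
        return arc
    runmax = np.maximum.accumulate(traj.x)
    if stuck_from == "last_progress":
        t_ref = traj.times[int(np.argmax(runmax))]
    elif stuck_from == "last_max_entry":
        at_max = np.nonzero(traj.x >= runmax[-1] - 1e-12)[0]
        t_ref = traj.times[int(at_max[-1])]
    else:
        raise ValueError(f"unknown stuck_from {stuck_from!r}")
    mean_speed = arc / traj.duration if traj.duration > 0 else 0.0
    return arc + mean_speed * float(traj.times[-1] - t_ref)


def strip_confinement(traj: Trajectory) -> float:
    """Width (cm) of the minimal horizontal strip containing the path."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(traj.y.max() - traj.y.min())


def performance_ratio(
    sim_records: pd.DataFrame, reference_records: pd.DataFrame
) -> float:
    """Density-averaged penalty-adjusted arc ratio, sim over reference.

    Both tables need ``coverage_bin`` (or ``maze_id``-free density keys)
    and ``penalty_adjusted`` columns; the per-density means are averaged
    unweighted and the two averages divided.  The reference may be
    empirical trajectories or any other model's records.
    """
    key = "coverage_bin" if "coverage_bin" in sim_records.columns else "coverage"
    sim_means = sim_records.groupby(key)["penalty_adjusted"].mean()
    ref_means = reference_records.groupby(key)["penalty_adjusted"].mean()
    if set(sim_means.index) != set(ref_means.index):
        raise ValueError("record sets cover different density grids")
    return float(sim_means.mean() / ref_means.mean())


_MODEL_RUNNERS = {
    "pinball": lambda maze, field, seed, pin, resp: simulate_pinball(
        maze, pin, seed=seed
    ),
    "discrete_rw": lambda maze, field, seed, pin, resp: simulate_discrete_rw(
        maze, seed=seed
    ),
    "extended_pinball": lambda maze, field, seed, pin, resp:
        simulate_extended_pinball(maze, None, resp, bias_field=field, seed=seed),
    "random_rebias": lambda maze, field, seed, pin, resp:
        simulate_local_responsive(
            maze, pin, resp, variant="random_rebias", seed=seed
        ),
    "altered_noise": lambda maze, field, seed, pin, resp:
        simulate_local_responsive(
            maze, pin, resp, variant="altered_noise", variant_param=2.0, seed=seed
        ),
}


def run_benchmark(
    models: list[str],
    cube_counts: list[int],
    n_mazes: int = 5,
    n_reps: int = 20,
    seed: int = 0,
    board: BoardSpec | None = None,
    pin: PinballParams | None = None,
    resp: ResponsiveParams | None = None,
    cell_size: float = 0.1,
) -> pd.DataFrame:
    """Seeded model-by-density sweep returning one row per run.

    Deterministic for a fixed master seed: maze seeds derive from
    ``(seed, cube_count, maze index)`` and run seeds from
    ``(seed, model, maze, rep)``.  The bias field is computed once per
    maze and shared by all extended-model runs on it.
    """
    board = board or BoardSpec()
    resp = resp or ResponsiveParams()
    unknown = set(models) - set(_MODEL_RUNNERS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    rows = []
    maze_id = 0
    for count in cube_counts:
        for m_i in range(n_mazes):
            msub = int(np.random.SeedSequence((seed, count, m_i)).generate_state(1)[0])
            maze = generate_cube_maze(count, board, seed=msub)
            cov = coverage(maze, cell_size)
            field = None
            if "extended_pinball" in models:
                grid = access_grid(maze, cell_size)
                field = compute_bias_field(maze, grid, resp.r_sense)
            for model in models:
                for rep in range(n_reps):
                    rsub = int(
                        np.random.SeedSequence(
                            (seed, zlib.crc32(model.encode()), maze_id, rep)
                        ).generate_state(1)[0]
                    )
                    traj = _MODEL_RUNNERS[model](maze, field, rsub, pin, resp)
                    rows.append(
                        BenchmarkRecord(
                            model=model,
                            maze_id=maze_id,
                            coverage=cov,
                            success=traj.outcome == "solved",
                            duration=traj.duration,
                            arc_length=traj.arc_length(),
                            penalty_adjusted=penalty_adjusted_arc(traj),
                            seed=rsub,
                        )
                    )
            maze_id += 1
    table = pd.DataFrame([asdict(r) for r in rows])
    if len(table):
        table["coverage_bin"] = table.groupby(
            table["maze_id"] // max(n_mazes, 1)
        )["coverage"].transform("mean")
    return table


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per model and density: success probability and arc statistics.

    Success carries a binomial standard error, arcs the standard error
    of the mean.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        p = g["success"].mean()
        return pd.Series(
            {
                "n": n,
                "success_prob": p,
                "success_se": math.sqrt(p * (1 - p) / n) if n else math.nan,
                "mean_penalty_arc": g["penalty_adjusted"].mean(),
                "penalty_arc_se": g["penalty_adjusted"].sem(),
            }
        )

    return (
        records.groupby(["model", "coverage_bin"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )
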