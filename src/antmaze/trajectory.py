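"""Time-stamped load-center paths: the common currency of all simulators.

Empirical and simulated paths share this representation, so every metric
(arc length, crossing statistics, trap-level performance, strip
confinement) applies to either.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trajectory", "trajectory_to_csv", "trajectory_from_csv"]

#: allowed obstacle penetration at any sample, cm
CONTACT_TOLERANCE = 0.01


@dataclass(frozen=True)
class Trajectory:
    """Load-center positions over time with the run's outcome.

    ``times`` (s, strictly increasing) and ``positions`` (cm, shape
    ``(n, 2)``) sample the path; ``outcome`` is ``"solved"`` when the load
    reached the nest edge and ``"timed_out"`` otherwise.  ``model`` tags
    the generating simulator (or ``"empirical"`` for loaded data).
    """

    times: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    outcome: str
    seed: int | None = None
    model: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if p.ndim != 2 or p.shape[1] != 2 or len(t) != len(p):
            raise ValueError("positions must be (n, 2) aligned with times")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.outcome not in ("solved", "timed_out"):
            raise ValueError("outcome must be 'solved' or 'timed_out'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def arc_length(self) -> float:
        seg = np.diff(self.positions, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Write ``t, x, y, model, seed, outcome`` rows (metadata repeated)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "x", "y", "model", "seed", "outcome"])
        seed = "" if traj.seed is None else traj.seed
        for t, (x, y) in zip(traj.times, traj.positions):
            writer.writerow([t, x, y, traj.model, seed, traj.outcome])


def trajectory_from_csv(path: str | Path) -> Trajectory:
    """Read a trajectory CSV; bare ``t, x, y`` files load as empirical."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = [h.strip().lower() for h in rows[0]]
    it, ix, iy = header.index("t"), header.index("x"), header.index("y")
    times = np.array([float(r[it]) for r in rows[1:]])
    pos = np.array([[float(r[ix]), float(r[iy])] for r in rows[1:]])
    model = rows[1][header.index("model")] if "model" in header else "empirical"
    outcome = rows[1][header.index("outcome")] if "outcome" in header else "timed_out"
    seed = None
    if "seed" in header and rows[1][header.index("seed")] != "":
        seed = int(rows[1][header.index("seed")])
    return Trajectory(times=times, positions=pos, outcome=outcome, seed=seed, model=model)
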