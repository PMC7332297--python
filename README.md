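# antmaze

Simulation and analysis toolkit for **collective navigation through
disordered environments**: how a disc-shaped load, carried cooperatively
toward a nest, crosses a board littered with randomly placed square
obstacles, and what a moderately extended sensing range buys compared
with purely local, physics-like strategies.

The package is aimed at researchers in collective animal behaviour and
movement ecology who want to reproduce, probe or extend the computational
side of this problem: percolation geometry of random cube mazes, trap
statistics, agent-based transport simulators, and discrete
ant-in-a-labyrinth navigation on bond-percolation lattices.

## The models

**Continuous cube mazes.** Square obstacles of edge *a* = 0.8 cm are
spread uniformly (without overlap) over a 70 × 50 cm board; the load is a
disc of radius *R* = 1.1 cm starting at (0, 25) and biased toward the
open edge at *x* = 70. The load's configuration space is the board minus
the Minkowski sum of every cube with a disc of radius *R*; **coverage** is
the board fraction inaccessible to the load's center. Random 300-cube
boards average ≈55% coverage, and the solvable-maze fraction collapses
at ≈60% — the continuous percolation threshold of this geometry.

**Pinball model.** The load is a damped disc "falling" toward the nest:
bias acceleration *g*, linear drag *μv*, and a Brownian force of
standard deviation *σ_F* redrawn every Δt = 0.04 s, with frictionless
zero-restitution collisions so the disc rolls around obstacle corners.
Fitted constants (μ = 10, g = 5.05, σ_F = 1277.8, m = 14.8571, in the
engine's native millimetre-scale length unit) give a free terminal speed
*mg/μ* ≈ 0.75 cm/s and an unobstructed crossing in ≈90 s.

**Responsive models.** A load that advances less than Δx_min = 0.2 cm
over 3 s is *stuck*. Local variants react blindly (temporary noise
change, or a random temporary bias direction). The **extended-sensing
pinball model** instead redirects its bias along a precomputed
direction field that encodes the surrounding trap structure out to a
sensing radius *r_sense* (default 10 cm — the distance scout ants guide
the group from): it walks the blocking obstacle's boundary *r_sense* cm
both ways, aims at each piece's most escape-ward point, and keeps the
direction closer to the nest.

**Traps.** Each connected dilated-obstacle blob that blocks forward
motion is a trap; its depth *D* is the escape geodesic from its deepest
point (advance 3.2 cm beyond the entry *x*, deduct the 3.2 cm). Below
the 55% coverage regime, the vast majority of traps have *D* < 10 cm —
which is why a 10 cm sensing range is so effective.

**Discrete lattices.** On bond-percolation lattices just above the
threshold (*p* = 0.55, which is 1/2 exactly for the square lattice), the
package implements biased random walks (`p_right = 0.25 + B`,
drift-maximizing bias *B* ≈ 0.045), strip-constrained vs. free shortest
paths (*D̃* vs. *D*), and the logarithmic extended-vision bout walker,
which crosses the lattice orders of magnitude faster than the best
biased walk.

## Worked example

```python
import numpy as np
from antmaze import (generate_cube_maze, coverage, access_grid, find_traps,
                     simulate_pinball, simulate_extended_pinball, crossing_metrics)

maze = generate_cube_maze(200, seed=7)
print(f"coverage: {coverage(maze):.3f}")

grid = access_grid(maze)
traps = find_traps(maze, grid)
finite = [t.depth for t in traps if np.isfinite(t.depth)]
print(f"traps: {len(traps)}, deepest {max(finite):.1f} cm, "
      f"{np.mean([d <= 10 for d in finite]):.0%} shallower than 10 cm")

for name, traj in [("pinball", simulate_pinball(maze, seed=0)),
                   ("extended", simulate_extended_pinball(maze, seed=0))]:
    ok, t, arc = crossing_metrics(traj)
    print(f"{name:9s} solved={ok} time={t:.0f} s arc={arc:.0f} cm")
```

prints

```
coverage: 0.433
traps: 73, deepest 12.7 cm, 97% shallower than 10 cm
pinball   solved=True time=296 s arc=343 cm
extended  solved=True time=141 s arc=123 cm
```

A 200-cube maze at 43% coverage decomposes into 73 traps, nearly all
shallower than the sensing range. The pinball model escapes traps only
through noise and needs a 343 cm path; the extended-sensing model's
redirected escapes cross the same maze in half the time with roughly a
third of the path length.

There is also a CLI (`antmaze generate|simulate|traps|lattice|benchmark|
report|percolation`) wrapping the same functions; every command takes
`--seed` and writes CSV/JSON artifacts.

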