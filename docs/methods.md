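# Methods

This note records the models implemented in `antmaze`, the assumptions
and numerical choices behind them, and the limits of what the synthetic
experiments can show.

## Environments

**Cube mazes.** `generate_cube_maze` places `n` squares of edge
`a = 0.8` cm on a `70 x 50` cm board by rejection sampling: rotation
uniform on `[0, pi/2)` (square symmetry), center uniform over positions
keeping the footprint inside the board, candidate accepted iff its
footprint overlaps no placed cube (tangency allowed; overlap is decided
by a separating-axis test that agrees with exact polygon intersection).
One PRNG stream per maze is derived from `(master seed, maze index)`, so
ensembles are order-independent and bit-reproducible. Placement is
capped at 10^6 attempts per maze.

The fixtures (`make_toy_trap`) are axis-aligned: one cube, a U-shaped
cup whose measured escape depth tracks `2 x arm_length + 2.65` cm (the
constant is the fixed lateral detour around one arm at the default
4 cm interior width), and a V wedge with its apex toward the nest.

**Bond lattices.** `generate_bond_lattice` opens each edge of an
`ny x nx` grid independently with probability `p`. The standard
construction for navigation experiments is `N` columns by
`delta*log2(N)` rows (`delta = 120`) with a concentric internal strip of
`alpha*log2(N)` rows (`alpha = 20`); all logarithms in lattice formulas
are base 2.

## Configuration-space geometry

The load is a disc of radius `R = 1.1` cm, so its configuration space is
the board minus each cube footprint dilated by a true disc (rounded
corners; one isolated cube blocks `(a+2R)^2 - (4-pi)R^2 = 7.961` cm^2)
and minus an `R`-wide margin along the three walls; the nest edge
(`x = width`) is open. Rasters use cell centers at half-cell offsets,
default cell size `h = 0.1` cm (the discrete walker's step); coverage
and path lengths change by under 1% when `h` is halved. Connectivity is
8-neighbour for both free space and obstacle blobs. Geodesics are
chamfer paths (diagonal step `sqrt(2) h`, within ~8% of true Euclidean
geodesics) computed with a minimum-cost-path engine; unit tests pin them
to an independent Dijkstra oracle exactly.

**Coverage convention.** Coverage is the fraction of the whole board
inaccessible to the load's center — dilated cubes *plus* wall margins.
Under this convention random 300-cube boards average ≈56% coverage and
the solvability threshold sits at ≈60%; restricting the numerator to
the cube field alone (available via `include_wall_margin=False`, used by
the closed-form unit tests) shifts these to ≈50% and ≈55%. The
all-inaccessible reading is the one consistent with accessibility
images of the arena and is the package default.

**Solvability and threshold.** A maze is solvable when an 8-connected
accessible path joins the start (snapped within 2 cm of `(0, height/2)`)
to any accessible cell of the last column. The percolation curve sweeps
cube counts, and the threshold estimate is the coverage at which an
isotonic (non-increasing) fit of the solvable fraction crosses 1/2.

## Traps

A point is *blocked* when blob cells sit within 0.25 cm directly ahead
(+x) of it — the same forward-ray test the bias-field algorithm uses, so
trap membership and responsive behaviour always agree. Each blob with at
least one blocked point is a trap. Its depth is

    D = max over blocked q of geodesic(q, {x >= x_q + 3.2 cm}) - 3.2,

clipped at zero; the 3.2 cm advance guarantees the trap is genuinely
cleared. Because every 8-connected path into the escape half-plane
enters through the first column of that region, the batched
implementation runs one multi-source chamfer transform per blocked
column (early-stopped at that column's blocked cells), which keeps a
300-cube maze under ~2 s at `h = 0.2` cm. Ties in the deepest-point
maximization break toward smaller x, then smaller y. Blocked points in
pockets sealed off from their escape set get `D = inf` (counted as
difficult); traps whose escape set leaves the board (nest-edge abutment)
are flagged and excluded from statistics. The depth statistic pools
mazes with measured coverage ≤ 0.55, matching the regime in which the
~94% small-trap fraction is defined.

Trap-crossing segments begin when a trajectory first comes within 1 cm
of the trap's blob, end once it advances 3.2 cm past the entry x, deduct
the 3.2 cm and normalize by `D`.

## The pinball engine

Semi-implicit Euler at `dt = 0.04` s with impulse-based, zero-restitution,
frictionless contacts against oriented squares: the disc is projected out
of penetration along the contact normal (closest point on the square) and
only the inward normal velocity is removed, so tangential sliding makes
the disc roll around corners. Wedged multi-contact configurations use up
to 40 alternating projection passes; if no feasible contact point exists
ahead (a slit narrower than the disc), the step is rejected and momentum
dropped — the disc cannot advance there. Residual penetration never
exceeds the 0.01 cm contact tolerance (asserted in tests). The noise
force has a uniformly random direction and a signed normal magnitude,
which is distributionally identical to the folded alternative; an AR(1)
correlated-noise scheme is available behind `noise_ar1`.

**Engine length unit.** The fitted constants (`mu = 10, g = 5.05,
sigma_F = 1277.8, m = 14.8571`) are kept verbatim but interpreted in the
source engine's native millimetre-scale unit (`ENGINE_UNIT = 0.1` cm per
unit). This is the only reading under which the model's own free-board
behaviour is self-consistent: terminal speed `m g / mu = 0.75` cm/s and
an unobstructed crossing in ≈90 s (under the 1.5-minute free-crossing
benchmark the constants were fitted to), with the 4.48 s redirected
escapes travelling ≈3.4 cm — commensurate with the 10 cm sensing radius
rather than overshooting it threefold as a 1 cm reading would.

The low-persistence noise variant (`sigma_F = 250` redrawn every 0.4 s)
runs on the same integrator with the 0.4 s update realized as a noise
hold; integrating at a literal 0.4 s timestep would tunnel through
0.8 cm cubes.

The discrete biased random walk takes `S = 0.1` cm axis steps with
`p_right = 0.25 + B` and `p_left = p_up = p_down = 0.25 - B/3`
(`B = 0.2211` fitted, free drift `4SB/3 = 0.0295` cm/step), redraws
blocked proposals up to 50 times, and waits in place if all directions
are blocked.

## Responsive models

The stuck detector compares the *absolute* net x displacement over a
3 s window against 0.2 cm (strict inequality); a load kicked backward
has moved and is not stalled. A stuck event lasts `t_changed = 4.48` s,
followed by a `t_cooldown = 4` s detector blackout. Local variants
rescale the noise amplitude during the event (`altered_noise`) or draw a
uniformly random temporary bias direction (`random_rebias`);
`noise_scale` is the non-responsive amplitude sweep.

The extended-sensing model redirects the (constant-magnitude) bias along
the precomputed field value at the nearest defined cell within 1.5 cm of
the load, falling back to the unchanged bias. The field lives on a
0.5 cm grid; for each cell center the algorithm (1) snaps centers inside
a blob to its boundary, dropping fully interior squares, (2) drops cells
with no blob within 0.25 cm directly ahead, (3) seeds at the blocking
blob's nearest boundary point, (4) walks the boundary contour `r_sense`
cm both ways, (5) takes each piece's minimum-x point, (6) rotates each
seed-to-point direction 15° away from the blob interior (so the ray
clears the blob), and (7) keeps the direction with the larger x
component. Boundaries come from sub-cell iso-contours of the dilated
mask; blobs clipped by the board edge use the edge as their boundary
continuation. For deep traps both candidate points lie inside the trap
and the direction points backward — the intended degradation at small
`r_sense`. Re-acquiring the field direction while stuck (boundary
following) is available via `follow_field` but off by default: the state
machine acquires one direction per event.

The extended model runs on time-correlated noise throughout: the
low-persistence amplitude held in 0.4 s blocks. This pairing keeps the
kicks comparable to the terminal speed so a redirected bias can actually
be followed, and its no-redirection control (correlated noise alone)
performs *worse* than the plain pinball model — responsiveness, not the
noise statistics, carries the improvement.

## Lattice navigation

Connected components, multi-source BFS distances and the biased walker
are compiled kernels operating directly on the edge masks, so full
`N = 8000` constructions (~12M nodes) resolve in seconds and `N = 70000`
is feasible (minutes per lattice, large memory). `D` is the shortest
open-edge path from the strip rows of the first column to those of the
last; `D~` restricts every vertex to the strip band. The bout walker
BFS-es inside its `2 gamma log2(N)` vision square to the strip column
`gamma log2(N)` ahead; if that column is unreachable in the window it
targets the reachable strip node with the greatest column advance, and
failing that enlarges the window once by 2x. Walkers may leave the strip;
only bout goals are strip-bound. Drift speed is net column advance per
step over walks capped at 150,000 steps (the cap binds at these sizes,
so speed is measured on terminated walks), and the traversal speedup is
`(span / best drift) / bout-walk length`. Closed-edge proposals are
redrawn, matching the continuous walker's re-selection rule.

## Problem sizes and what the experiments show

Default experiment sizes — 30–50 mazes per density, `h = 0.2` cm for
trap sweeps, `N = 2000` lattices (20 instances) for bias sweeps, three
`N = 8000` instances for strip-path excess, 200 x 200 lattices for the
spanning sweep — were chosen so the full acceptance battery completes on
a laptop-class machine while keeping Monte-Carlo errors well inside the
tolerance of each check.

The generators emulate the *statistical* structure of the experimental
arenas (uniform non-overlapping obstacle placement, Bernoulli edges);
they do not reproduce any specific experimental configuration, camera
distortion, or the ants' own trajectories, so passing tests validate the
algorithms and their ensemble statistics, not agreement with any
individual empirical run. Two further limitations are worth naming:

* At desk scale the strip-path excess (~0–0.5% for `N` up to 8000) and
  the extended-vision speedup (~120-fold at `N = 500–2000`) are flat in
  `N` within Monte-Carlo noise; the size trends only emerge at scales
  beyond the default experiments.
* The contact model is ideal (frictionless, zero restitution), which
  makes undirected force noise unusually effective at trap escape: the
  extended-sensing model dominates every other simulator on
  penalty-adjusted arc length and on deep single traps, but its
  whole-maze *success probability* runs slightly below the plain
  pinball model's rather than above it. The corresponding ordering
  check in the acceptance suite is left failing by design — it records
  a real property of this engine, not a tolerance choice.
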