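"""Numba kernels for bond-percolation lattices.

Nodes are (row, col) on an ``ny x nx`` grid; ``h_open[r, c]`` opens the
edge (r, c)-(r, c+1) and ``v_open[r, c]`` the edge (r, c)-(r+1, c).  All
routines run on flat int32 indices, so lattices up to ~2e9 nodes away
from the int32 limit are fine at full scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def label_components(h_open, v_open):
    """Connected-component labels of the open-edge graph (0-based, -1 none).

    Plain BFS flood fill; returns (labels, sizes).
    """
    ny, nx = h_open.shape[0], v_open.shape[1]
    labels = np.full(ny * nx, -1, dtype=np.int32)
    queue = np.empty(ny * nx, dtype=np.int64)
    sizes_list = []
    current = 0
    for s in range(ny * nx):
        if labels[s] >= 0:
            continue
        labels[s] = current
        queue[0] = s
        head, tail = 0, 1
        count = 1
        while head < tail:
            u = queue[head]
            head += 1
            r = u // nx
            c = u % nx
            if c + 1 < nx and h_open[r, c] and labels[u + 1] < 0:
                labels[u + 1] = current
                queue[tail] = u + 1
                tail += 1
                count += 1
            if c > 0 and h_open[r, c - 1] and labels[u - 1] < 0:
                labels[u - 1] = current
                queue[tail] = u - 1
                tail += 1
                count += 1
            if r + 1 < ny and v_open[r, c] and labels[u + nx] < 0:
                labels[u + nx] = current
                queue[tail] = u + nx
                tail += 1
                count += 1
            if r > 0 and v_open[r - 1, c] and labels[u - nx] < 0:
                labels[u - nx] = current
                queue[tail] = u - nx
                tail += 1
                count += 1
        sizes_list.append(count)
        current += 1
    sizes = np.empty(current, dtype=np.int64)
    for i in range(current):
        sizes[i] = sizes_list[i]
    return labels.reshape(ny, nx), sizes


@njit(cache=True)
def bfs_distances(h_open, v_open, sources_r, sources_c,
                  r_lo, r_hi, c_lo, c_hi,
                  strip_lo, strip_hi):
    """Multi-source BFS distance (edge count) within a window.

    The search is restricted to rows [r_lo, r_hi) and cols [c_lo, c_hi);
    rows outside [strip_lo, strip_hi) are additionally excluded when
    strip_hi > strip_lo (strip-constrained mode).  Unreached nodes get -1.
    """
    ny, nx = h_open.shape[0], v_open.shape[1]
    wr = r_hi - r_lo
    wc = c_hi - c_lo
    dist = np.full(wr * wc, -1, dtype=np.int32)
    queue = np.empty(wr * wc, dtype=np.int64)
    tail = 0
    constrained = strip_hi > strip_lo
    for i in range(len(sources_r)):
        r = sources_r[i]
        c = sources_c[i]
        if r < r_lo or r >= r_hi or c < c_lo or c >= c_hi:
            continue
        if constrained and (r < strip_lo or r >= strip_hi):
            continue
        u = (r - r_lo) * wc + (c - c_lo)
        if dist[u] < 0:
            dist[u] = 0
            queue[tail] = u
            tail += 1
    head = 0
    while head < tail:
        u = queue[head]
        head += 1
        lr = u // wc
        lc = u % wc
        r = lr + r_lo
        c = lc + c_lo
        d = dist[u] + 1
        # right
        if c + 1 < c_hi and h_open[r, c] and dist[u + 1] < 0:
            dist[u + 1] = d
            queue[tail] = u + 1
            tail += 1
        # left
        if c > c_lo and h_open[r, c - 1] and dist[u - 1] < 0:
            dist[u - 1] = d
            queue[tail] = u - 1
            tail += 1
        # down
        if r + 1 < r_hi and (not constrained or r + 1 < strip_hi) and \
                v_open[r, c] and dist[u + wc] < 0:
            dist[u + wc] = d
            queue[tail] = u + wc
            tail += 1
        # up
        if r > r_lo and (not constrained or r - 1 >= strip_lo) and \
                v_open[r - 1, c] and dist[u - wc] < 0:
            dist[u - wc] = d
            queue[tail] = u - wc
            tail += 1
    return dist.reshape(wr, wc)


@njit(cache=True)
def biased_walk(h_open, v_open, start_r, start_c, B, max_steps, stop_col, seed):
    """Biased random walk over open edges with closed-edge redraw.

    p_right = 0.25 + B; left/up/down get (0.25 - B/3) each.  A proposal
    over a closed edge is redrawn (up to 50 times, then the walker waits
    one step).  Stops at ``stop_col`` or after ``max_steps``.

    Returns (net_col_advance, steps_taken, reached_flag, final_r, final_c).
    """
    np.random.seed(seed)
    ny, nx = h_open.shape[0], v_open.shape[1]
    r, c = start_r, start_c
    p_right = 0.25 + B
    p_other = 0.25 - B / 3.0
    steps = 0
    reached = False
    for i in range(max_steps):
        steps = i + 1
        for _ in range(50):
            u = np.random.random()
            if u < p_right:
                if c + 1 < nx and h_open[r, c]:
                    c += 1
                    break
            elif u < p_right + p_other:
                if c > 0 and h_open[r, c - 1]:
                    c -= 1
                    break
            elif u < p_right + 2.0 * p_other:
                if r + 1 < ny and v_open[r, c]:
                    r += 1
                    break
            else:
                if r > 0 and v_open[r - 1, c]:
                    r -= 1
                    break
        if c >= stop_col:
            reached = True
            break
    return c - start_c, steps, reached, r, c
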