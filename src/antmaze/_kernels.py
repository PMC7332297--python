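"""Numba inner loops for the continuous simulators.

The moving body is a disc of radius ``R``; obstacles are oriented squares.
Contacts are zero-restitution and frictionless: the disc is projected out
of penetration along the contact normal and only the inward normal
velocity component is removed, so tangential sliding is retained and the
disc rolls around corners.  A uniform spatial hash over cube centers keeps
per-step collision work local.

All randomness comes from ``np.random`` seeded inside the kernel, so a
fixed seed reproduces a run bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# walker state-machine modes
FREE, STUCK = 0, 1

# responsive variants
PLAIN, ALTERED_NOISE, RANDOM_REBIAS, EXTENDED = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _closest_point_dist(x, y, cx, cy, ca, sa, half):
    """Distance from (x, y) to an oriented square and the outward normal.

    Returns (dist, nx, ny); for a point inside the footprint dist is
    negative (depth to the nearest face) and the normal points out of
    that face.
    """
    dx = x - cx
    dy = y - cy
    lx = ca * dx + sa * dy
    ly = -sa * dx + ca * dy
    ox = abs(lx) - half
    oy = abs(ly) - half
    if ox > 0.0 or oy > 0.0:
        px = ox if ox > 0.0 else 0.0
        py = oy if oy > 0.0 else 0.0
        d = math.sqrt(px * px + py * py)
        if d > 0.0:
            nlx = (math.copysign(px, lx)) / d
            nly = (math.copysign(py, ly)) / d
        else:
            nlx, nly = 1.0, 0.0
        nx = ca * nlx - sa * nly
        ny = sa * nlx + ca * nly
        return d, nx, ny
    # center inside the footprint: push out through the nearest face
    if ox > oy:
        nlx, nly = math.copysign(1.0, lx), 0.0
        d = ox
    else:
        nlx, nly = 0.0, math.copysign(1.0, ly)
        d = oy
    nx = ca * nlx - sa * nly
    ny = sa * nlx + ca * nly
    return d, nx, ny


@njit(cache=True, inline="always")
def _resolve_contacts(x, y, vx, vy, R, W, H,
                      cubes, trig, cell_start, cell_items, ncx, ncy, csz):
    """Project the disc out of all penetrations (alternating projections).

    Wedged configurations (disc between two cubes, or cube and wall)
    converge geometrically; 40 passes leave residuals far below the
    0.01 cm contact tolerance.
    """
    for _ in range(40):
        moved = False
        # walls: x=0, y=0, y=H; the nest edge x=W is open
        if x < R:
            x = R
            if vx < 0.0:
                vx = 0.0
            moved = True
        if y < R:
            y = R
            if vy < 0.0:
                vy = 0.0
            moved = True
        if y > H - R:
            y = H - R
            if vy > 0.0:
                vy = 0.0
            moved = True
        ci = int(x / csz)
        cj = int(y / csz)
        pen = False
        for ii in range(ci - 1, ci + 2):
            if ii < 0 or ii >= ncx:
                continue
            for jj in range(cj - 1, cj + 2):
                if jj < 0 or jj >= ncy:
                    continue
                idx = ii * ncy + jj
                for t in range(cell_start[idx], cell_start[idx + 1]):
                    k = cell_items[t]
                    d, nx, ny = _closest_point_dist(
                        x, y, cubes[k, 0], cubes[k, 1], trig[k, 0], trig[k, 1],
                        trig[k, 2],
                    )
                    if d < R:
                        push = R - d + 1e-9
                        x += nx * push
                        y += ny * push
                        vn = vx * nx + vy * ny
                        if vn < 0.0:
                            vx -= vn * nx
                            vy -= vn * ny
                        pen = True
        if pen:
            moved = True
        if not moved:
            break
    return x, y, vx, vy


@njit(cache=True, inline="always")
def _min_cube_dist(x, y, cubes, trig, cell_start, cell_items, ncx, ncy, csz):
    best = 1e30
    ci = int(x / csz)
    cj = int(y / csz)
    for ii in range(ci - 1, ci + 2):
        if ii < 0 or ii >= ncx:
            continue
        for jj in range(cj - 1, cj + 2):
            if jj < 0 or jj >= ncy:
                continue
            idx = ii * ncy + jj
            for t in range(cell_start[idx], cell_start[idx + 1]):
                k = cell_items[t]
                d, _, _ = _closest_point_dist(
                    x, y, cubes[k, 0], cubes[k, 1], trig[k, 0], trig[k, 1],
                    trig[k, 2],
                )
                if d < best:
                    best = d
    return best


@njit(cache=True)
def pinball_run(
    cubes, trig, cell_start, cell_items, ncx, ncy, csz,
    W, H, R,
    mass, g, sigma_f, mu, dt, max_steps,
    x0, y0, seed,
    noise_block, noise_folded, ar1,
    variant, variant_param,
    stuck_sigma, stuck_noise_block, reacquire,
    dxmin, n_compare, n_changed, n_cooldown,
    field_defined, field_dx, field_dy, field_pitch,
):
    """Integrate one pinball-family trajectory.

    ``variant`` selects the responsive behaviour on a stuck event
    (0 plain, 1 altered noise, 2 random re-bias, 3 extended-sensing bias
    field); ``n_compare <= 0`` disables the stuck detector entirely.
    Returns (positions, n_steps, solved, events, n_events) where events
    rows are (step, 1=stuck / 2=revert).
    """
    np.random.seed(seed)
    pos = np.empty((max_steps + 1, 2))
    max_ev = max_steps // max(n_changed, 1) + 4 if n_compare > 0 else 1
    events = np.empty((max_ev, 2), dtype=np.int64)
    n_ev = 0

    x, y = x0, y0
    vx, vy = 0.0, 0.0
    x, y, vx, vy = _resolve_contacts(
        x, y, vx, vy, R, W, H, cubes, trig, cell_start, cell_items, ncx, ncy, csz
    )
    pos[0, 0] = x
    pos[0, 1] = y

    bias_x, bias_y = 1.0, 0.0
    sigma_eff = sigma_f
    mode = FREE
    stuck_until = -1
    cooldown_until = -1
    xbuf = np.empty(max(n_compare, 1))
    nux, nuy = 0.0, 0.0
    solved = False
    n = 0
    inv_m = 1.0 / mass
    for i in range(max_steps):
        if n_compare > 0:
            xbuf[i % n_compare] = x
        # noise force: uniform direction, signed normal magnitude
        block = stuck_noise_block if (mode == STUCK and stuck_noise_block > 0) else noise_block
        # boundary following: while stuck, track the field of the current cell
        if mode == STUCK and variant == EXTENDED and reacquire == 1 and i % block == 0:
            bx, by, ok = _field_lookup(
                x, y, field_defined, field_dx, field_dy, field_pitch
            )
            if ok:
                bias_x, bias_y = bx, by
        if ar1 > 0.0:
            mag = np.random.normal(0.0, sigma_eff)
            phi = np.random.uniform(0.0, 2.0 * math.pi)
            nux = ar1 * nux + math.sqrt(1.0 - ar1 * ar1) * mag * math.cos(phi)
            nuy = ar1 * nuy + math.sqrt(1.0 - ar1 * ar1) * mag * math.sin(phi)
        elif i % block == 0:
            mag = np.random.normal(0.0, sigma_eff)
            if noise_folded:
                mag = abs(mag)
            phi = np.random.uniform(0.0, 2.0 * math.pi)
            nux = mag * math.cos(phi)
            nuy = mag * math.sin(phi)
        ax = g * bias_x + nux * inv_m - mu * inv_m * vx
        ay = g * bias_y + nuy * inv_m - mu * inv_m * vy
        vx += dt * ax
        vy += dt * ay
        xp, yp = x, y
        x += dt * vx
        y += dt * vy
        x, y, vx, vy = _resolve_contacts(
            x, y, vx, vy, R, W, H, cubes, trig, cell_start, cell_items, ncx, ncy, csz
        )
        # narrow wedge between obstacles: no feasible contact point ahead,
        # so the disc cannot advance — stay put and drop its momentum
        if (
            _min_cube_dist(x, y, cubes, trig, cell_start, cell_items, ncx, ncy, csz)
            < R - 0.005
        ):
            x, y = xp, yp
            vx, vy = 0.0, 0.0
        n = i + 1
        pos[n, 0] = x
        pos[n, 1] = y
        if x >= W:
            solved = True
            break
        # stuck-detection state machine
        if n_compare > 0:
            if mode == STUCK:
                if n >= stuck_until:
                    mode = FREE
                    bias_x, bias_y = 1.0, 0.0
                    sigma_eff = sigma_f
                    cooldown_until = n + n_cooldown
                    events[n_ev, 0] = n
                    events[n_ev, 1] = 2
                    n_ev += 1
            elif n >= n_compare and n >= cooldown_until:
                x_then = xbuf[n % n_compare]
                if abs(x - x_then) < dxmin:
                    mode = STUCK
                    stuck_until = n + n_changed
                    events[n_ev, 0] = n
                    events[n_ev, 1] = 1
                    n_ev += 1
                    if variant == ALTERED_NOISE:
                        sigma_eff = sigma_f * variant_param
                    elif variant == RANDOM_REBIAS:
                        ang = np.random.uniform(0.0, 2.0 * math.pi)
                        bias_x = math.cos(ang)
                        bias_y = math.sin(ang)
                    elif variant == EXTENDED:
                        bx, by, ok = _field_lookup(
                            x, y, field_defined, field_dx, field_dy, field_pitch
                        )
                        if ok:
                            bias_x, bias_y = bx, by
                        if stuck_sigma >= 0.0:
                            sigma_eff = stuck_sigma
    return pos[: n + 1], n, solved, events, n_ev


@njit(cache=True, inline="always")
def _field_lookup(x, y, defined, fdx, fdy, pitch):
    """Bias direction at the nearest defined field cell within 1.5 cm."""
    nyf, nxf = defined.shape
    j0 = int(x / pitch)
    i0 = int(y / pitch)
    w = int(1.5 / pitch) + 1
    best = 1.5 * 1.5
    bx, by = 0.0, 0.0
    ok = False
    for i in range(i0 - w, i0 + w + 1):
        if i < 0 or i >= nyf:
            continue
        for j in range(j0 - w, j0 + w + 1):
            if j < 0 or j >= nxf:
                continue
            if defined[i, j] == 0:
                continue
            cx = (j + 0.5) * pitch
            cy = (i + 0.5) * pitch
            d2 = (cx - x) ** 2 + (cy - y) ** 2
            if d2 <= best:
                best = d2
                bx, by = fdx[i, j], fdy[i, j]
                ok = True
    return bx, by, ok


@njit(cache=True)
def discrete_rw_run(
    cubes, trig, cell_start, cell_items, ncx, ncy, csz,
    W, H, R,
    S, B, max_steps,
    x0, y0, seed,
):
    """Biased four-direction random walk of the disc over a continuous maze.

    p_right = 0.25 + B toward the nest, the other three directions share
    the remainder equally (0.25 - B/3).  A proposal overlapping a cube or
    wall is redrawn; if 50 consecutive proposals are blocked the walker
    stays put for that step.
    """
    np.random.seed(seed)
    pos = np.empty((max_steps + 1, 2))
    x, y = x0, y0
    pos[0, 0] = x
    pos[0, 1] = y
    p_right = 0.25 + B
    p_other = 0.25 - B / 3.0
    solved = False
    n = 0
    for i in range(max_steps):
        for _ in range(50):
            u = np.random.random()
            if u < p_right:
                nx_, ny_ = x + S, y
            elif u < p_right + p_other:
                nx_, ny_ = x - S, y
            elif u < p_right + 2.0 * p_other:
                nx_, ny_ = x, y + S
            else:
                nx_, ny_ = x, y - S
            if nx_ < R or ny_ < R or ny_ > H - R:
                continue
            d = _min_cube_dist(
                nx_, ny_, cubes, trig, cell_start, cell_items, ncx, ncy, csz
            )
            if d < R - 1e-12:
                continue
            x, y = nx_, ny_
            break
        n = i + 1
        pos[n, 0] = x
        pos[n, 1] = y
        if x >= W:
            solved = True
            break
    return pos[: n + 1], n, solved
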