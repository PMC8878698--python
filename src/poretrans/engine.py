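"""Low-level jitted kernels for the sequential-algorithm mover.

The lattice world is a dense int32 grid ``world[x + ox, y + oy]`` holding
``0`` for a free node, ``-1`` for a membrane wall node and ``i + 1`` when
chain segment ``i`` occupies the node.  The grid is sized so that a chain
anchored in or around the slab can never reach its edge (see
:func:`poretrans.mover._make_world`); out-of-grid targets are treated as
blocked.

All kernels share one piece of mutable state per run: the coordinate arrays
``xs, ys``, the occupancy grid, and a 2-slot counter array
``counters = [n_trans, n_nonneg]`` tracking how many segments sit at
``x >= L`` and ``x >= 0``.  Randomness comes from numba's internal Mersenne
Twister, seeded explicitly at every public entry point, so trajectories are
a pure function of the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TRANSLOCATED = 1
RETRACTED = 2
STUCK = 3

MOORE = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)
VON_NEUMANN = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)], dtype=np.int64)


@njit(cache=True, inline="always")
def _dist2(dx, dy, cheb):
    if cheb:
        a = abs(dx)
        b = abs(dy)
        d = a if a > b else b
        return d * d
    return dx * dx + dy * dy


@njit(cache=True, inline="always")
def _apply_step(j, tx, ty, xs, ys, world, ox, oy, L, counters, undo_idx, undo_x, undo_y, nundo):
    old_x = xs[j]
    old_y = ys[j]
    world[old_x + ox, old_y + oy] = 0
    world[tx + ox, ty + oy] = j + 1
    xs[j] = tx
    ys[j] = ty
    if old_x >= L and tx < L:
        counters[0] -= 1
    elif old_x < L and tx >= L:
        counters[0] += 1
    if old_x >= 0 and tx < 0:
        counters[1] -= 1
    elif old_x < 0 and tx >= 0:
        counters[1] += 1
    undo_idx[nundo] = j
    undo_x[nundo] = old_x
    undo_y[nundo] = old_y
    return nundo + 1


@njit(cache=True)
def _move_core(
    xs,
    ys,
    world,
    ox,
    oy,
    L,
    counters,
    dirs,
    dmin2,
    dmax2,
    cheb,
    bias_dir,
    bias_sel,
    undo_idx,
    undo_x,
    undo_y,
    cand_x,
    cand_y,
    cand_w,
):
    """One move attempt: initiator step plus tension cascade, atomic on failure.

    Returns ``(accepted, steps_taken, initiator)``.
    """
    N = xs.size
    gx_max = world.shape[0]
    gy_max = world.shape[1]
    ndirs = dirs.shape[0]

    # --- initiator: weight 1 + bias_sel for in-pore segments (rejection sampling)
    wmax = 1.0 + bias_sel
    init = 0
    while True:
        init = np.random.randint(0, N)
        if xs[init] >= 0 and xs[init] < L:
            break
        if np.random.random() * wmax <= 1.0:
            break

    # --- allowed steps of the initiator, with the +x classes up-weighted in pore
    x0 = xs[init]
    y0 = ys[init]
    inpore = x0 >= 0 and x0 < L
    r = (1.0 + bias_dir) / (1.0 - bias_dir)
    ncand = 0
    for k in range(ndirs):
        tx = x0 + dirs[k, 0]
        ty = y0 + dirs[k, 1]
        gx = tx + ox
        gy = ty + oy
        if gx < 0 or gx >= gx_max or gy < 0 or gy >= gy_max:
            continue
        if world[gx, gy] != 0:
            continue
        cand_x[ncand] = tx
        cand_y[ncand] = ty
        cand_w[ncand] = r if (inpore and dirs[k, 0] > 0) else 1.0
        ncand += 1
    if ncand == 0:
        return 0, 0, init

    tot = 0.0
    for k in range(ncand):
        tot += cand_w[k]
    u = np.random.random() * tot
    pick = ncand - 1
    acc = 0.0
    for k in range(ncand):
        acc += cand_w[k]
        if u < acc:
            pick = k
            break

    nundo = 0
    nundo = _apply_step(
        init, cand_x[pick], cand_y[pick], xs, ys, world, ox, oy, L, counters, undo_idx, undo_x, undo_y, nundo
    )
    steps = 1
    ok = True

    # --- tension cascade, lower-index side first, each segment at most once
    for side in range(2):
        j = init - 1 if side == 0 else init + 1
        step = -1 if side == 0 else 1
        while 0 <= j < N:
            moved = j - step  # neighbour on the already-moved side
            d2 = _dist2(xs[j] - xs[moved], ys[j] - ys[moved], cheb)
            if d2 >= dmin2 and d2 <= dmax2:
                break
            nres = 0
            for k in range(ndirs):
                tx = xs[j] + dirs[k, 0]
                ty = ys[j] + dirs[k, 1]
                gx = tx + ox
                gy = ty + oy
                if gx < 0 or gx >= gx_max or gy < 0 or gy >= gy_max:
                    continue
                if world[gx, gy] != 0:
                    continue
                d2b = _dist2(tx - xs[moved], ty - ys[moved], cheb)
                if d2b >= dmin2 and d2b <= dmax2:
                    cand_x[nres] = tx
                    cand_y[nres] = ty
                    nres += 1
            if nres == 0:
                ok = False
                break
            pick = np.random.randint(0, nres)
            nundo = _apply_step(
                j, cand_x[pick], cand_y[pick], xs, ys, world, ox, oy, L, counters, undo_idx, undo_x, undo_y, nundo
            )
            steps += 1
            j += step
        if not ok:
            break

    if not ok:
        # atomic rollback, reverse order
        for t in range(nundo - 1, -1, -1):
            jj = undo_idx[t]
            cx = xs[jj]
            cy = ys[jj]
            bx = undo_x[t]
            by = undo_y[t]
            world[cx + ox, cy + oy] = 0
            world[bx + ox, by + oy] = jj + 1
            if cx >= L and bx < L:
                counters[0] -= 1
            elif cx < L and bx >= L:
                counters[0] += 1
            if cx >= 0 and bx < 0:
                counters[1] -= 1
            elif cx < 0 and bx >= 0:
                counters[1] += 1
            xs[jj] = bx
            ys[jj] = by
        return 0, 0, init
    return 1, steps, init


@njit(cache=True)
def move_once(seed, xs, ys, world, ox, oy, L, counters, dirs, dmin2, dmax2, cheb, bias_dir, bias_sel):
    """Seed the kernel RNG and perform a single move attempt."""
    np.random.seed(seed)
    N = xs.size
    undo_idx = np.empty(N, np.int64)
    undo_x = np.empty(N, np.int64)
    undo_y = np.empty(N, np.int64)
    cand_x = np.empty(dirs.shape[0], np.int64)
    cand_y = np.empty(dirs.shape[0], np.int64)
    cand_w = np.empty(dirs.shape[0], np.float64)
    return _move_core(
        xs, ys, world, ox, oy, L, counters, dirs, dmin2, dmax2, cheb, bias_dir, bias_sel,
        undo_idx, undo_x, undo_y, cand_x, cand_y, cand_w,
    )


@njit(cache=True)
def run_core(seed, xs, ys, world, ox, oy, L, counters, dirs, dmin2, dmax2, cheb, bias_dir, bias_sel, max_moves):
    """Full translocation run; every attempt counts one unit of time.

    Returns ``(outcome, attempts)`` with outcome in
    ``{TRANSLOCATED, RETRACTED, STUCK}``.
    """
    np.random.seed(seed)
    N = xs.size
    undo_idx = np.empty(N, np.int64)
    undo_x = np.empty(N, np.int64)
    undo_y = np.empty(N, np.int64)
    cand_x = np.empty(dirs.shape[0], np.int64)
    cand_y = np.empty(dirs.shape[0], np.int64)
    cand_w = np.empty(dirs.shape[0], np.float64)
    attempts = 0
    accepted = 0
    while attempts < max_moves:
        acc, _, _ = _move_core(
            xs, ys, world, ox, oy, L, counters, dirs, dmin2, dmax2, cheb, bias_dir, bias_sel,
            undo_idx, undo_x, undo_y, cand_x, cand_y, cand_w,
        )
        attempts += 1
        accepted += acc
        if counters[0] == N:
            return TRANSLOCATED, attempts, accepted
        if counters[1] == 0:
            return RETRACTED, attempts, accepted
    return STUCK, attempts, accepted
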