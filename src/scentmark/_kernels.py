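"""Compiled inner loop of the territory simulator.

The kernel advances every animal once per time-step (randomized
sequential order), consuming pre-drawn uniforms so that its trajectory
is bit-identical to the pure-Python reference stepper in
:mod:`scentmark.sim` given the same random stream.  Per animal and step
three uniforms are used: one to rank the update order, one for the
uniform move choice and one for the correlated-retreat decision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_chunk"]


@njit(cache=True)
def step_chunk(
    pos,  # (N, 2) int64, wrapped coordinates (y == 0 in 1D)
    upos,  # (N, 2) int64, unwrapped displacement bookkeeping
    heading,  # (N, 2) int64, last move vector (0,0 before first move)
    nsince,  # (N,) int64, steps since last foreign-scent encounter
    last_visit,  # (N, S) float64, -inf == never visited
    time0,  # int64, time before the first step of this chunk
    nsteps,  # int64, steps to advance
    L,
    dims,
    tas,  # float64, np.inf == never expires
    correlated,  # bool
    q0,
    lam0,
    R,  # (nsteps, 3, N) float64 pre-drawn uniforms
    rec_stride,  # int64, record positions when t % rec_stride == 0
    pos_out,  # (n_rec, N, 2) int64, slot t // rec_stride
    upos_out,  # (n_rec, N, 2) int64
    snap_times,  # (n_snap,) int64 ascending
    snaps_out,  # (n_snap, N, S) float64
    snap_ptr,  # int64, next snapshot slot
):
    N = pos.shape[0]
    stride = L if dims == 2 else 1
    ndir = 2 * dims
    # direction table: +x, -x, +y, -y
    dx = np.array([1, -1, 0, 0], dtype=np.int64)
    dy = np.array([0, 0, 1, -1], dtype=np.int64)
    adm = np.empty(4, dtype=np.int64)
    w = np.empty(4, dtype=np.float64)

    for k in range(nsteps):
        tnew = time0 + k + 1
        order = np.argsort(R[k, 0])
        for oi in range(N):
            i = order[oi]
            x = pos[i, 0]
            y = pos[i, 1]
            s = x * stride + y
            # does the current site carry active foreign scent?
            enc = False
            for j in range(N):
                if j != i and tnew - last_visit[j, s] < tas:
                    enc = True
                    break
            # admissible moves
            nadm = 0
            for d in range(ndir):
                nx = (x + dx[d]) % L
                ny = (y + dy[d]) % L
                ok = True
                if enc:
                    ns = nx * stride + ny
                    for j in range(N):
                        if j != i and tnew - last_visit[j, ns] < tas:
                            ok = False
                            break
                if ok:
                    adm[nadm] = d
                    nadm += 1
            if enc:
                n_new = 0
            else:
                n_new = nsince[i] + 1
            nsince[i] = n_new
            if nadm > 0:
                chosen = -1
                has_heading = heading[i, 0] != 0 or heading[i, 1] != 0
                if correlated and n_new >= 1 and has_heading:
                    decay = 2.0 ** (-float(min(n_new - 1, 1024)))
                    if dims == 1:
                        q = q0 * decay
                        hd = -1
                        for a in range(nadm):
                            if dx[adm[a]] == heading[i, 0]:
                                hd = a
                                break
                        if hd >= 0 and R[k, 2, i] < q:
                            chosen = hd
                    else:
                        lam = lam0 * decay
                        wsum = 0.0
                        for a in range(nadm):
                            d = adm[a]
                            dot = dx[d] * heading[i, 0] + dy[d] * heading[i, 1]
                            w[a] = np.exp(-lam * (1 - dot))
                            wsum += w[a]
                        u = R[k, 2, i] * wsum
                        c = 0.0
                        chosen = nadm - 1
                        for a in range(nadm):
                            c += w[a]
                            if u < c:
                                chosen = a
                                break
                if chosen < 0:
                    chosen = int(R[k, 1, i] * nadm)
                    if chosen >= nadm:
                        chosen = nadm - 1
                d = adm[chosen]
                x = (x + dx[d]) % L
                y = (y + dy[d]) % L
                pos[i, 0] = x
                pos[i, 1] = y
                upos[i, 0] += dx[d]
                upos[i, 1] += dy[d]
                heading[i, 0] = dx[d]
                heading[i, 1] = dy[d]
            # stamp own scent at the (possibly unchanged) site
            last_visit[i, x * stride + y] = tnew
        if rec_stride > 0 and tnew % rec_stride == 0:
            slot = tnew // rec_stride
            for i in range(N):
                pos_out[slot, i, 0] = pos[i, 0]
                pos_out[slot, i, 1] = pos[i, 1]
                upos_out[slot, i, 0] = upos[i, 0]
                upos_out[slot, i, 1] = upos[i, 1]
        if snap_ptr < snap_times.shape[0] and tnew == snap_times[snap_ptr]:
            snaps_out[snap_ptr] = last_visit
            snap_ptr += 1
    return snap_ptr
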