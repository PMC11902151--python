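"""Numba kernel for exact kinetic Monte Carlo simulation of the QEIRQ lattice.

Direct-method Gillespie with a two-level (blocked) propensity index: per-cell
propensities are kept in a flat array and block sums are recomputed exactly on
every local update, so the sampling structure never accumulates floating-point
drift.  Events touch only the firing cell and, when the cell enters or leaves
an inducing substate, its <= 6 neighbors, so updates are O(block size).

The kernel accumulates the activity kymograph (number of E/I cells per layer,
sampled at time-bin midpoints) on the fly and can optionally log every event,
which the pure-Python audit paths replay.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOCK = 64

#: Kernel exit codes.
OK = 0
EVENT_OVERFLOW = 1


@njit(cache=True, inline="always")
def _refresh_block(prop, bsum, block):
    lo = block * BLOCK
    hi = min(lo + BLOCK, prop.shape[0])
    s = 0.0
    for i in range(lo, hi):
        s += prop[i]
    bsum[block] = s


@njit(cache=True)
def _sample_cell(prop, bsum, target):
    """Pick the cell at cumulative propensity ``target``; -1 if none."""
    acc = 0.0
    nb = bsum.shape[0]
    for b in range(nb):
        if acc + bsum[b] > target:
            lo = b * BLOCK
            hi = min(lo + BLOCK, prop.shape[0])
            for i in range(lo, hi):
                acc += prop[i]
                if acc > target:
                    return i
            # numerical residue: fall through to the last positive cell
            for i in range(hi - 1, lo - 1, -1):
                if prop[i] > 0.0:
                    return i
        else:
            acc += bsum[b]
    for i in range(prop.shape[0] - 1, -1, -1):
        if prop[i] > 0.0:
            return i
    return -1


@njit(cache=True)
def run_ssa(
    nbr,            # (n_cells, 6) int32 neighbor indices, -1 padded
    nbr_cnt,        # (n_cells,) int8 neighbor counts
    width,          # int
    length,         # int
    first_i,        # first inducing state code
    first_r,        # first refractory state code
    last_r,         # last refractory state code
    inv_tau_act,    # activation rate per inducing neighbor
    state_rates,    # (n_states,) spontaneous exit rate per code (0 for Q)
    init_times,     # (n_init,) float64 sorted initiation times
    t_max,          # float64
    binw,           # kymograph bin width (min)
    seed,           # int
    state,          # (n_cells,) int16, modified in place (initial condition)
    kymo,           # (length, n_bins) int32, filled in place
    ev_time,        # (cap,) float64 event log buffers (cap may be 0)
    ev_cell,        # (cap,) int32
    ev_from,        # (cap,) int16
    ev_to,          # (cap,) int16
    record_events,  # bool
):
    np.random.seed(seed)
    n_cells = state.shape[0]
    n_bins = kymo.shape[1]
    n_blocks = (n_cells + BLOCK - 1) // BLOCK

    prop = np.zeros(n_cells, np.float64)
    bsum = np.zeros(n_blocks, np.float64)
    i_cnt = np.zeros(n_cells, np.int8)       # inducing neighbors per cell
    act = np.zeros(length, np.int32)          # active (E/I) cells per layer

    # initial propensities from the supplied state grid
    for c in range(n_cells):
        s = state[c]
        if s >= first_i and s < first_r:
            for j in range(nbr_cnt[c]):
                i_cnt[nbr[c, j]] += 1
    for c in range(n_cells):
        s = state[c]
        if s == 0:
            prop[c] = i_cnt[c] * inv_tau_act
        else:
            prop[c] = state_rates[s]
            if s < first_r:
                act[c // width] += 1
    for b in range(n_blocks):
        _refresh_block(prop, bsum, b)

    t = 0.0
    next_bin = 0
    next_init = 0
    n_ev = 0
    cap = ev_time.shape[0]

    while True:
        total = 0.0
        for b in range(n_blocks):
            total += bsum[b]

        if total <= 0.0:
            if next_init >= init_times.shape[0]:
                break  # frozen lattice, nothing scheduled: early stop
            t_next = init_times[next_init]
        else:
            t_next = t - np.log(np.random.random()) / total
        do_init = next_init < init_times.shape[0] and init_times[next_init] <= t_next
        if do_init:
            t_next = init_times[next_init]
        if t_next > t_max:
            t_next = t_max

        # record kymograph columns at bin midpoints passed by this step
        while next_bin < n_bins and (next_bin + 0.5) * binw <= t_next:
            for x in range(length):
                kymo[x, next_bin] = act[x]
            next_bin += 1

        if t_next >= t_max:
            t = t_max
            break
        t = t_next

        if do_init:
            # scheduled initiation: quiescent layer-0 cells become I_1
            next_init += 1
            for r in range(width):
                c = r  # layer-major indexing: layer 0 cells are 0..width-1
                if state[c] == 0:
                    if record_events:
                        if n_ev >= cap:
                            return EVENT_OVERFLOW, n_ev, t
                        ev_time[n_ev] = t
                        ev_cell[n_ev] = c
                        ev_from[n_ev] = 0
                        ev_to[n_ev] = first_i
                        n_ev += 1
                    state[c] = first_i
                    act[0] += 1
                    prop[c] = state_rates[first_i]
                    _refresh_block(prop, bsum, c // BLOCK)
                    for j in range(nbr_cnt[c]):
                        nb = nbr[c, j]
                        i_cnt[nb] += 1
                        if state[nb] == 0:
                            prop[nb] = i_cnt[nb] * inv_tau_act
                            _refresh_block(prop, bsum, nb // BLOCK)
            continue

        # fire one reaction
        cell = _sample_cell(prop, bsum, np.random.random() * total)
        if cell < 0:
            continue
        s = state[cell]
        if s == 0:
            new = 1                      # activation Q -> E_1
        elif s == last_r:
            new = 0                      # recovery R_nR -> Q
        else:
            new = s + 1
        if record_events:
            if n_ev >= cap:
                return EVENT_OVERFLOW, n_ev, t
            ev_time[n_ev] = t
            ev_cell[n_ev] = cell
            ev_from[n_ev] = s
            ev_to[n_ev] = new
            n_ev += 1
        state[cell] = new

        layer = cell // width
        if s == 0:
            act[layer] += 1              # became excited
        elif s + 1 == first_r:
            act[layer] -= 1              # left the inducing state

        if new == 0:
            prop[cell] = i_cnt[cell] * inv_tau_act
        else:
            prop[cell] = state_rates[new]
        _refresh_block(prop, bsum, cell // BLOCK)

        if new == first_i and s + 1 == first_i:
            # entered I: neighbors gain an inducing neighbor
            for j in range(nbr_cnt[cell]):
                nb = nbr[cell, j]
                i_cnt[nb] += 1
                if state[nb] == 0:
                    prop[nb] = i_cnt[nb] * inv_tau_act
                    _refresh_block(prop, bsum, nb // BLOCK)
        elif new == first_r:
            # left I: neighbors lose an inducing neighbor
            for j in range(nbr_cnt[cell]):
                nb = nbr[cell, j]
                i_cnt[nb] -= 1
                if state[nb] == 0:
                    prop[nb] = i_cnt[nb] * inv_tau_act
                    _refresh_block(prop, bsum, nb // BLOCK)

    # lattice frozen (or t_max hit): remaining bins hold the final counts
    while next_bin < n_bins:
        for x in range(length):
            kymo[x, next_bin] = act[x]
        next_bin += 1

    return OK, n_ev, t
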