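"""Compiled inner loop of the division sweep.

The sweep visits the "ripe" cells (age >= tau) of one time step in a
pre-drawn random order and applies, per cell: quiescence if no free site
exists in the 2-Moore neighborhood, mitotic death with probability ``p_m``
if treatment is active, otherwise division onto a uniformly chosen free
neighbor site.  All randomness (visit order, death rolls, neighbor choices)
is drawn beforehand from a numpy Generator and passed in, so the compiled
path is bit-identical to the pure-Python reference in
:func:`tumorca.engine._ripe_sweep_py`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

QUIESCENT = 1
PROLIFERATING = 0


@njit(cache=False)
def ripe_sweep(
    grid,          # int64 (L, L): cell index per site, -1 empty
    rows, cols,    # int64 (n,)
    tau, age,      # float64 (n,)
    state,         # uint8 (n,)
    alive,         # bool (n,), all True on entry
    order,         # int64 (k,): ripe-cell indices in visit order
    rolls,         # float64 (k,): mitotic death rolls
    choice_u,      # float64 (k,): free-site choice uniforms
    p_m,           # float64: mitotic death prob; < 0 disables mitotic death
    d_rows, d_cols, d_tau,  # preallocated (k,) outputs for daughters
):
    L = grid.shape[0]
    n = rows.shape[0]
    nd = 0
    births = 0
    mdeaths = 0
    fr = np.empty(24, np.int64)
    fc = np.empty(24, np.int64)
    for k in range(order.shape[0]):
        i = order[k]
        if not alive[i]:
            continue
        r = rows[i]
        c = cols[i]
        nfree = 0
        for dr in range(-2, 3):
            rr = r + dr
            if rr < 0 or rr >= L:
                continue
            for dc in range(-2, 3):
                if dr == 0 and dc == 0:
                    continue
                cc = c + dc
                if cc < 0 or cc >= L:
                    continue
                if grid[rr, cc] == -1:
                    fr[nfree] = rr
                    fc[nfree] = cc
                    nfree += 1
        if nfree == 0:
            state[i] = QUIESCENT
            continue
        if p_m >= 0.0 and rolls[k] < p_m:
            alive[i] = False
            grid[r, c] = -1
            mdeaths += 1
            continue
        j = int(choice_u[k] * nfree)
        if j >= nfree:
            j = nfree - 1
        d_rows[nd] = fr[j]
        d_cols[nd] = fc[j]
        d_tau[nd] = tau[i]
        grid[fr[j], fc[j]] = n + nd
        nd += 1
        age[i] = 0.0
        state[i] = PROLIFERATING
        births += 1
    return nd, births, mdeaths
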