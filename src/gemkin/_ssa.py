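"""Gillespie direct-method cores.

Two variants over the same random-number stream (so an event-recorded
and a grid-recorded run with the same seed follow the identical sample
path): one records every reaction event (times + reaction indices), the
other records states on a fixed time grid and accumulates the exact
time integral (AUC) of every species on the fly.

The cores are compiled with numba when available; the pure-Python
fallbacks use ``numpy.random.RandomState``, which draws the same
MT19937 sequence as numba's internal generator, so results are
identical either way.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def _propensities(k, order, ra, rb, x, a):
    a0 = 0.0
    for j in range(k.size):
        o = order[j]
        if o == 0:
            aj = k[j]
        elif o == 1:
            aj = k[j] * x[ra[j]]
        else:
            ia, ib = ra[j], rb[j]
            if ia == ib:
                n = x[ia]
                aj = k[j] * n * (n - 1.0) * 0.5
            else:
                aj = k[j] * x[ia] * x[ib]
        a[j] = aj
        a0 += aj
    return a0


def _ssa_grid(k, order, ra, rb, net, x0, t_end, grid, seed):
    """Run SSA to t_end; return (states on grid, exact per-species AUC)."""
    np.random.seed(seed)
    R = k.size
    S = x0.size
    G = grid.size
    x = x0.astype(np.float64).copy()
    out = np.zeros((G, S))
    auc = np.zeros(S)
    a = np.zeros(R)
    t = 0.0
    gi = 0
    while True:
        a0 = _propensities(k, order, ra, rb, x, a)
        if a0 <= 0.0:
            t_next = t_end + 1.0  # absorbing: hold state to the end
        else:
            t_next = t - np.log(np.random.random()) / a0
        if t_next >= t_end:
            dt = t_end - t
            for i in range(S):
                auc[i] += x[i] * dt
            while gi < G:
                for i in range(S):
                    out[gi, i] = x[i]
                gi += 1
            break
        while gi < G and grid[gi] < t_next:
            for i in range(S):
                out[gi, i] = x[i]
            gi += 1
        dt = t_next - t
        for i in range(S):
            auc[i] += x[i] * dt
        u = np.random.random() * a0
        c = 0.0
        jj = R - 1
        for j in range(R):
            c += a[j]
            if u < c:
                jj = j
                break
        for i in range(S):
            x[i] += net[jj, i]
        t = t_next
    return out, auc


def _ssa_events(k, order, ra, rb, net, x0, t_end, seed, cap):
    """Run SSA recording every event; return (times, reaction idx, count).

    ``count == cap`` signals capacity overflow; the caller re-runs with a
    larger buffer (the seeded stream makes the re-run identical).
    """
    np.random.seed(seed)
    R = k.size
    S = x0.size
    x = x0.astype(np.float64).copy()
    times = np.zeros(cap)
    rxns = np.zeros(cap, dtype=np.int64)
    a = np.zeros(R)
    t = 0.0
    n = 0
    while n < cap:
        a0 = _propensities(k, order, ra, rb, x, a)
        if a0 <= 0.0:
            break
        t_next = t - np.log(np.random.random()) / a0
        if t_next >= t_end:
            break
        u = np.random.random() * a0
        c = 0.0
        jj = R - 1
        for j in range(R):
            c += a[j]
            if u < c:
                jj = j
                break
        for i in range(S):
            x[i] += net[jj, i]
        times[n] = t_next
        rxns[n] = jj
        n += 1
        t = t_next
    return times, rxns, n


if HAVE_NUMBA:
    _propensities = njit(cache=False)(_propensities)
    ssa_grid = njit(cache=False)(_ssa_grid)
    ssa_events = njit(cache=False)(_ssa_events)
else:  # pragma: no cover
    ssa_grid = _ssa_grid
    ssa_events = _ssa_events
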