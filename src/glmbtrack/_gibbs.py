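"""Systematic-scan Gibbs kernel for ranked-assignment sampling.

One categorical decision variable per (track / birth / spawn) candidate with
options {die-or-absent, miss, z_1 ... z_m}; measurement options are mutually
exclusive across variables.  Compiled with numba for throughput; the chain's
stationary distribution is proportional to the product of selected option
weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gibbs_sweeps(log_costs, n_meas, n_sweeps, init, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n_vars, n_opts = log_costs.shape
    cur = init.copy()
    owner = np.full(n_meas, -1, dtype=np.int64)
    for v in range(n_vars):
        if cur[v] >= 2:
            owner[cur[v] - 2] = v
    out = np.empty((n_sweeps, n_vars), dtype=np.int32)
    w = np.empty(n_opts)
    for s in range(n_sweeps):
        for v in range(n_vars):
            if cur[v] >= 2:
                owner[cur[v] - 2] = -1
            mx = -np.inf
            for o in range(n_opts):
                free = o < 2 or owner[o - 2] < 0
                if free and log_costs[v, o] > mx:
                    mx = log_costs[v, o]
            total = 0.0
            for o in range(n_opts):
                free = o < 2 or owner[o - 2] < 0
                if free and np.isfinite(log_costs[v, o]):
                    w[o] = np.exp(log_costs[v, o] - mx)
                else:
                    w[o] = 0.0
                total += w[o]
            if total <= 0.0:
                pick = cur[v]  # no feasible option: keep current value
            else:
                u = np.random.random() * total
                acc = 0.0
                pick = 0
                for o in range(n_opts):
                    acc += w[o]
                    if u <= acc:
                        pick = o
                        break
            cur[v] = pick
            if pick >= 2:
                owner[pick - 2] = v
        out[s] = cur
    return out
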