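"""Hot loops (degree-preserving rewiring, permutation search) as numba kernels.

Randomness is pre-drawn with numpy Generators by the callers, so results are
bit-reproducible and the kernels themselves are pure functions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def double_edge_swap(u, v, adj, e1, e2, flip):
    """Attempt a sequence of degree-preserving double-edge swaps in place.

    ``u``, ``v``: endpoint arrays of the current edge list (modified).
    ``adj``: boolean adjacency (modified).  ``e1``/``e2``/``flip``: one
    pre-drawn proposal per attempt.  A proposal (a,b),(c,d) becomes
    (a,d),(c,b); it is rejected if the four vertices are not distinct or
    either new edge already exists.  Returns the number of successful swaps.
    """
    successes = 0
    for t in range(e1.shape[0]):
        i = e1[t]
        j = e2[t]
        if i == j:
            continue
        a = u[i]
        b = v[i]
        c = u[j]
        d = v[j]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        u[i] = a
        v[i] = d
        u[j] = c
        v[j] = b
        successes += 1
    return successes


@njit(cache=True)
def bandwidth_search(pos, indptr, indices, prop_u, prop_v, f0, trace):
    """Greedy random-transposition search minimising total edge bandwidth.

    ``pos`` maps node -> position (modified in place).  Each proposal swaps
    the positions of nodes ``prop_u[t]`` and ``prop_v[t]`` and is accepted
    iff the objective sum(|pos[i]-pos[j]|) over edges does not increase.
    ``trace[t]`` records the objective after attempt t.  Returns the final
    objective.
    """
    f = f0
    for t in range(prop_u.shape[0]):
        a = prop_u[t]
        b = prop_v[t]
        if a == b:
            trace[t] = f
            continue
        pa = pos[a]
        pb = pos[b]
        delta = 0
        for k in range(indptr[a], indptr[a + 1]):
            w = indices[k]
            pw = pos[w]
            if w == b:
                pw = pa
            delta += abs(pb - pw) - abs(pa - pos[w])
        for k in range(indptr[b], indptr[b + 1]):
            w = indices[k]
            pw = pos[w]
            if w == a:
                pw = pb
            delta += abs(pa - pw) - abs(pb - pos[w])
        if delta <= 0:
            pos[a] = pb
            pos[b] = pa
            f += delta
        trace[t] = f
    return f
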