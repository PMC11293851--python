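"""Numba kernels for ERGM statistics, change statistics and MCMC sampling.

All kernels work on a dense symmetric 0/1 adjacency matrix ``A`` (int8,
zero diagonal) and the flat term arrays produced by
:meth:`benthicnet.ergm.model.ModelSpec.expand`:

- ``kinds``: int64 per expanded term (0 edges, 1 gwesp, 2 nodecov,
  3 nodefactor);
- ``vecs``: float64 ``(p, n)`` per-vertex values (covariate values or level
  indicators; zero rows for edges/gwesp);
- ``decay``: the fixed gwesp decay tau.

Vertex-based terms (nodecov, nodefactor) share the same change-statistic
form ``v[i] + v[j]``; gwesp uses the local shared-partner update, which
costs O(n * |common neighbours|) per toggle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_EDGES = 0
KIND_GWESP = 1
KIND_NODECOV = 2
KIND_NODEFACTOR = 3


@njit(cache=False)
def gwesp_from_adj(A, decay):
    """e^tau * sum_k [1 - (1 - e^-tau)^k] * EP_k from the adjacency matrix."""
    n = A.shape[0]
    u = 1.0 - np.exp(-decay)
    w = np.exp(decay)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                c = 0
                for k in range(n):
                    if k != i and k != j and A[i, k] and A[j, k]:
                        c += 1
                total += w * (1.0 - u**c)
    return total


@njit(cache=False)
def stats_from_adj(A, kinds, vecs, decay):
    """Full sufficient-statistic vector g(y) for the expanded model."""
    n = A.shape[0]
    p = kinds.shape[0]
    out = np.zeros(p)
    n_edges = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                n_edges += 1.0
    for t in range(p):
        kind = kinds[t]
        if kind == KIND_EDGES:
            out[t] = n_edges
        elif kind == KIND_GWESP:
            out[t] = gwesp_from_adj(A, decay)
        else:  # nodecov / nodefactor: sum of endpoint values over edges
            acc = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if A[i, j]:
                        acc += vecs[t, i] + vecs[t, j]
            out[t] = acc
    return out


@njit(cache=False)
def change_stats_absent(A, i, j, kinds, vecs, decay, out):
    """Delta g for ADDING edge (i, j); requires A[i, j] == 0.

    For gwesp the delta is e^tau*(1 - u^c) for the new edge (c = number of
    common neighbours of i and j) plus u^esp(e) for every edge e = (i,k) or
    (j,k) through a common neighbour k, whose shared-partner count rises by
    one.
    """
    n = A.shape[0]
    p = kinds.shape[0]
    gwesp_delta = 0.0
    need_gwesp = False
    for t in range(p):
        if kinds[t] == KIND_GWESP:
            need_gwesp = True
    if need_gwesp:
        u = 1.0 - np.exp(-decay)
        w = np.exp(decay)
        c = 0
        extra = 0.0
        for k in range(n):
            if k != i and k != j and A[i, k] and A[j, k]:
                c += 1
                p_ik = 0
                p_jk = 0
                for m in range(n):
                    if m != i and m != k and A[i, m] and A[k, m]:
                        p_ik += 1
                    if m != j and m != k and A[j, m] and A[k, m]:
                        p_jk += 1
                extra += u**p_ik + u**p_jk
        gwesp_delta = w * (1.0 - u**c) + extra
    for t in range(p):
        kind = kinds[t]
        if kind == KIND_EDGES:
            out[t] = 1.0
        elif kind == KIND_GWESP:
            out[t] = gwesp_delta
        else:
            out[t] = vecs[t, i] + vecs[t, j]
    return out


@njit(cache=False)
def mh_chain(A, kinds, vecs, decay, theta, burn_in, thin, n_samples, seed, collect_graphs):
    """Metropolis--Hastings tie-toggle chain.

    Proposes a uniform random dyad and toggles it with acceptance
    probability min(1, exp(s * theta . delta-g)), s = +1 for addition and
    -1 for deletion.  ``A`` is modified in place (the chain's final state).
    Returns the statistic vectors of the ``n_samples`` retained graphs
    (spaced ``thin`` toggles apart after ``burn_in`` toggles) and, when
    ``collect_graphs`` is true, the retained adjacency matrices.
    """
    np.random.seed(seed)
    n = A.shape[0]
    p = kinds.shape[0]
    g = stats_from_adj(A, kinds, vecs, decay)
    delta = np.zeros(p)
    stats_out = np.zeros((n_samples, p))
    n_keep = n_samples if collect_graphs else 1
    graphs_out = np.zeros((n_keep, n, n), dtype=np.int8)
    total = burn_in + thin * n_samples
    next_keep = burn_in + thin
    kept = 0
    for step in range(1, total + 1):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n - 1)
        if j >= i:
            j += 1
        if A[i, j]:
            A[i, j] = 0
            A[j, i] = 0
            change_stats_absent(A, i, j, kinds, vecs, decay, delta)
            logr = 0.0
            for t in range(p):
                logr -= theta[t] * delta[t]
            if np.log(np.random.random()) < logr:
                for t in range(p):
                    g[t] -= delta[t]
            else:
                A[i, j] = 1
                A[j, i] = 1
        else:
            change_stats_absent(A, i, j, kinds, vecs, decay, delta)
            logr = 0.0
            for t in range(p):
                logr += theta[t] * delta[t]
            if np.log(np.random.random()) < logr:
                A[i, j] = 1
                A[j, i] = 1
                for t in range(p):
                    g[t] += delta[t]
        if step == next_keep and kept < n_samples:
            for t in range(p):
                stats_out[kept, t] = g[t]
            if collect_graphs:
                for a in range(n):
                    for b in range(n):
                        graphs_out[kept, a, b] = A[a, b]
            kept += 1
            next_keep += thin
    return stats_out, graphs_out


@njit(cache=False)
def enum_stats(n, kinds, vecs, decay):
    """Sufficient statistics of every graph on n vertices (2^D rows).

    Graph m has edge (i, j), i < j, iff bit d of m is set, where d indexes
    dyads in row-major (i, j) order.  Only feasible for n <= 7.
    """
    D = n * (n - 1) // 2
    p = kinds.shape[0]
    n_graphs = 1 << D
    out = np.zeros((n_graphs, p))
    A = np.zeros((n, n), dtype=np.int8)
    for m in range(n_graphs):
        d = 0
        for i in range(n):
            for j in range(i + 1, n):
                bit = (m >> d) & 1
                A[i, j] = bit
                A[j, i] = bit
                d += 1
        s = stats_from_adj(A, kinds, vecs, decay)
        for t in range(p):
            out[m, t] = s[t]
    return out
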