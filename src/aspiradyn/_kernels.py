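"""Numba-compiled Monte-Carlo kernels for the Fermi decision function.

The simulator's hot loop — pick a focal individual, play one game, flip
with probability g(beta * (e - pi)) — is compiled here for the common case
in which every individual uses the Fermi function. Heterogeneous or
non-Fermi decision functions fall back to the pure-Python loop in
:mod:`aspiradyn.dynamics`.

Each kernel iterates ``n_steps`` elementary updates, discards ``burn_in``
of them and accumulates the abundance of strategy A into ``n_batches``
contiguous batches (batch means feed the standard-error estimate). The
legacy numba RNG is seeded once per run.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(inline="always")
def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def run_network_single(
    indptr, indices, a, b, e, beta, state, n_steps, burn_in, n_batches, seed
):
    """Single-game scheme on a network: coplayers drawn from the focal's
    neighborhood (the whole neighborhood when degree equals d-1)."""
    np.random.seed(seed)
    n = state.shape[0]
    d = a.shape[0]
    need = d - 1
    maxdeg = 0
    for i in range(n):
        deg = indptr[i + 1] - indptr[i]
        if deg > maxdeg:
            maxdeg = deg
    work = np.empty(maxdeg, dtype=np.int64)
    n_post = n_steps - burn_in
    batch_size = n_post // n_batches
    batches = np.zeros(n_batches)
    n_a = 0
    for i in range(n):
        n_a += state[i]
    t_post = 0
    for t in range(n_steps):
        i = np.random.randint(n)
        lo = indptr[i]
        deg = indptr[i + 1] - lo
        k = 0
        if deg == need:
            for j in range(lo, lo + deg):
                k += state[indices[j]]
        else:
            for j in range(deg):
                work[j] = indices[lo + j]
            for j in range(need):
                r = j + np.random.randint(deg - j)
                tmp = work[j]
                work[j] = work[r]
                work[r] = tmp
                k += state[work[j]]
        pi = a[k] if state[i] == 1 else b[k]
        if np.random.random() < _logistic(beta * (e[i] - pi)):
            if state[i] == 1:
                state[i] = 0
                n_a -= 1
            else:
                state[i] = 1
                n_a += 1
        if t >= burn_in and t_post < n_batches * batch_size:
            batches[t_post // batch_size] += n_a
            t_post += 1
    return batches / (batch_size * n)


@njit(cache=False)
def run_well_mixed_single(a, b, e, beta, state, n_steps, burn_in, n_batches, seed):
    """Single-game scheme, well-mixed: d-1 distinct coplayers resampled
    from the N-1 others at every payoff evaluation."""
    np.random.seed(seed)
    n = state.shape[0]
    d = a.shape[0]
    need = d - 1
    chosen = np.empty(need, dtype=np.int64)
    n_post = n_steps - burn_in
    batch_size = n_post // n_batches
    batches = np.zeros(n_batches)
    n_a = 0
    for i in range(n):
        n_a += state[i]
    t_post = 0
    for t in range(n_steps):
        i = np.random.randint(n)
        k = 0
        for j in range(need):
            while True:
                c = np.random.randint(n)
                if c == i:
                    continue
                dup = False
                for q in range(j):
                    if chosen[q] == c:
                        dup = True
                        break
                if not dup:
                    break
            chosen[j] = c
            k += state[c]
        pi = a[k] if state[i] == 1 else b[k]
        if np.random.random() < _logistic(beta * (e[i] - pi)):
            if state[i] == 1:
                state[i] = 0
                n_a -= 1
            else:
                state[i] = 1
                n_a += 1
        if t >= burn_in and t_post < n_batches * batch_size:
            batches[t_post // batch_size] += n_a
            t_post += 1
    return batches / (batch_size * n)


@njit(cache=False)
def run_network_averaged(
    indptr, indices, a, b, e, beta, state, n_steps, burn_in, n_batches, seed
):
    """Averaged scheme on a regular network of degree d-1: the focal's
    payoff is the mean over the d games organised by itself and by each
    neighbor, where each organiser's game comprises its closed
    neighborhood."""
    np.random.seed(seed)
    n = state.shape[0]
    d = a.shape[0]
    n_post = n_steps - burn_in
    batch_size = n_post // n_batches
    batches = np.zeros(n_batches)
    n_a = 0
    for i in range(n):
        n_a += state[i]
    t_post = 0
    for t in range(n_steps):
        i = np.random.randint(n)
        s_i = state[i]
        total = 0.0
        lo = indptr[i]
        deg = indptr[i + 1] - lo
        for gidx in range(deg + 1):
            o = i if gidx == deg else indices[lo + gidx]
            # A-count in o's closed neighborhood, minus the focal itself
            k = state[o] - s_i
            for j in range(indptr[o], indptr[o + 1]):
                k += state[indices[j]]
            total += a[k] if s_i == 1 else b[k]
        pi = total / (deg + 1)
        if np.random.random() < _logistic(beta * (e[i] - pi)):
            if state[i] == 1:
                state[i] = 0
                n_a -= 1
            else:
                state[i] = 1
                n_a += 1
        if t >= burn_in and t_post < n_batches * batch_size:
            batches[t_post // batch_size] += n_a
            t_post += 1
    return batches / (batch_size * n)
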