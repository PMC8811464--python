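"""Compiled inner loops for spike routing and procedural expansion.

These kernels replicate, bit for bit, the pure-Python generator
semantics in :mod:`procsnn.rng` (xorshift32 with the (13, 17, 5)
triple, top-bits index selection with rejection, strict ``h < H``
threshold comparison).  Equality of the two paths is asserted by the
test suite; the kernels exist purely so that simulations of
10^4..10^5-step runs stay cheap on one CPU core.

Layout conventions (shared with :mod:`procsnn.connectivity`):

* per-cluster seed tables are dense ``(n_clusters, n_sources)`` arrays
  of 32-bit seeds and 16-bit sequence lengths L;
* weight tables are ``(n_clusters, n_pops, ZW)`` with float32 values,
  delay tables ``(n_clusters, n_pops, ZD)`` with uint8 delay codes;
* target draws are uniform over the cluster size (an alias table whose
  thresholds are all one), realized as a rejected top-bits index draw
  followed by a discarded threshold draw so that stream consumption
  matches a regular TBRNG draw;
* per synapse the draw order is target N, delay D, weight J.

The delay ring buffers have 64 slots; a code D delivers at step
``t + D + 1``.
"""

import numpy as np
from numba import njit

M32 = np.uint64(0xFFFFFFFF)


@njit(cache=True)
def _xs32(x):
    """One xorshift32 step, triple (13, 17, 5); x is uint64 holding a
    32-bit value."""
    x = x ^ ((x << np.uint64(13)) & M32)
    x = x ^ (x >> np.uint64(17))
    x = x ^ ((x << np.uint64(5)) & M32)
    return x


@njit(cache=True)
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x ^ (x >> np.uint64(31))


@njit(cache=True)
def _scramble(seed):
    """Threshold-stream seed from the stored index-stream seed."""
    s = _splitmix64(seed) & M32
    if s == np.uint64(0):
        s = np.uint64(1)
    return s


@njit(cache=True)
def _uniform_index(state, z, nbits):
    """Top-bits index draw with rejection; returns (k, state).  nbits is
    ceil(log2 z); callers pass nbits == 0 for z == 1 (no draw consumed)."""
    if nbits == 0:
        return np.uint64(0), state
    shift = np.uint64(32 - nbits)
    while True:
        state = _xs32(state)
        k = state >> shift
        if k < np.uint64(z):
            return k, state


@njit(cache=True)
def _expand_axon_into(seed, L, spop, c, cluster_lo, cluster_size, tbits,
                      wH, wN, wA, dH, dN, dA,
                      out_J, out_D, out_N, base):
    """Expand one (seed, L, S) entry for one cluster into (J, D, N_global)
    triples written at out_*[base:base+L].  Returns base + L."""
    s_idx = seed
    s_thr = _scramble(seed)
    z = np.uint64(cluster_size)
    for i in range(L):
        # target: uniform over cluster, threshold draw discarded
        k, s_idx = _uniform_index(s_idx, z, tbits)
        s_thr = _xs32(s_thr)
        n_local = k
        # delay: z = 64 alias table
        k, s_idx = _uniform_index(s_idx, np.uint64(64), 6)
        s_thr = _xs32(s_thr)
        if s_thr < np.uint64(dH[c, spop, k]):
            code = dN[c, spop, k]
        else:
            code = dA[c, spop, k]
        # weight: z = 32 alias table
        k, s_idx = _uniform_index(s_idx, np.uint64(32), 5)
        s_thr = _xs32(s_thr)
        if s_thr < np.uint64(wH[c, spop, k]):
            w = wN[c, spop, k]
        else:
            w = wA[c, spop, k]
        out_J[base + i] = w
        out_D[base + i] = code
        out_N[base + i] = cluster_lo + np.int64(n_local)
    return base + L


@njit(cache=True)
def deliver_procedural(gids, t, ring_e, ring_i, L, seeds, pop_of, pop_is_exc,
                       cluster_lo, cluster_size, tbits,
                       wH, wN, wA, dH, dN, dA):
    """Route one step's spikes procedurally: for every spiking source and
    every cluster, re-expand the axon's synapse sequence and accumulate
    the weights into the delay ring at slot (t + D + 1) mod 64."""
    n_clusters = L.shape[0]
    for g in range(gids.shape[0]):
        gid = gids[g]
        spop = pop_of[gid]
        exc = pop_is_exc[spop]
        for c in range(n_clusters):
            l = L[c, gid]
            if l == 0:
                continue
            s_idx = seeds[c, gid]
            s_thr = _scramble(s_idx)
            z = np.uint64(cluster_size[c])
            tb = tbits[c]
            lo = cluster_lo[c]
            for i in range(l):
                k, s_idx = _uniform_index(s_idx, z, tb)
                s_thr = _xs32(s_thr)
                n_local = np.int64(k)
                k, s_idx = _uniform_index(s_idx, np.uint64(64), 6)
                s_thr = _xs32(s_thr)
                if s_thr < np.uint64(dH[c, spop, k]):
                    code = dN[c, spop, k]
                else:
                    code = dA[c, spop, k]
                k, s_idx = _uniform_index(s_idx, np.uint64(32), 5)
                s_thr = _xs32(s_thr)
                if s_thr < np.uint64(wH[c, spop, k]):
                    w = wN[c, spop, k]
                else:
                    w = wA[c, spop, k]
                slot = (t + np.int64(code) + 1) % 64
                tgt = lo + n_local
                if exc:
                    ring_e[slot, tgt] += w
                else:
                    ring_i[slot, tgt] += w


@njit(cache=True)
def deliver_explicit(gids, t, ring_e, ring_i, indptr, tgt, J, dcode,
                     pop_of, pop_is_exc):
    """Route one step's spikes through an explicit synapse list stored in
    CSR-by-source order (clusters ascending, draw order within)."""
    for g in range(gids.shape[0]):
        gid = gids[g]
        exc = pop_is_exc[pop_of[gid]]
        for s in range(indptr[gid], indptr[gid + 1]):
            slot = (t + np.int64(dcode[s]) + 1) % 64
            if exc:
                ring_e[slot, tgt[s]] += J[s]
            else:
                ring_i[slot, tgt[s]] += J[s]


@njit(cache=True)
def materialize_kernel(L, seeds, pop_of, cluster_lo, cluster_size, tbits,
                       wH, wN, wA, dH, dN, dA,
                       out_delta, out_J, out_D, out_N):
    """Expand every seed-table entry into explicit quadruples, ordered by
    (source gid, cluster, draw index) — the canonical CSR-by-source
    order used by the explicit backend."""
    n_clusters, n_sources = L.shape
    base = np.int64(0)
    for gid in range(n_sources):
        spop = pop_of[gid]
        for c in range(n_clusters):
            l = L[c, gid]
            if l == 0:
                continue
            end = _expand_axon_into(
                seeds[c, gid], l, spop, c, cluster_lo[c], cluster_size[c],
                tbits[c], wH, wN, wA, dH, dN, dA, out_J, out_D, out_N, base)
            for s in range(base, end):
                out_delta[s] = gid
            base = end
    return base
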