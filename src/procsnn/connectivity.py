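"""Procedural network representation: seed tables + MTBRNG fitting.

A network is stored not as an explicit synapse list but as, per
micro-cluster and per source axon, a triple (seed, L, S): a 32-bit
xorshift seed, the number L of synapses that axon makes inside the
cluster, and the selector S (the source's population).  Whenever the
source spikes, the cluster re-expands the axon by reseeding its
table-based generators and drawing exactly L (target, delay, weight)
triples — deterministically, so every expansion of the same axon yields
the same synapses.

The tables are fitted from a reference realization of the network: per
(cluster, source population) the weight distribution is fitted as a
normal and discretized to a 32-bin equal-probability alias table, the
delay-code distribution is taken over as an empirical 64-bin histogram
table, and targets are drawn uniformly over the cluster.  Sequence
lengths L are the exact per-source synapse counts of the reference
realization, so synapse counts are conserved and the multiplicity
distribution is reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .rng import (
    AliasTable,
    Mtbrng,
    Pmf,
    XorshiftState,
    build_alias_table,
    derive_seed,
    discretize_pdf,
    pmf_from_counts,
    tbrng_draw,
)

__all__ = [
    "SeedTableEntry",
    "NetworkRealization",
    "MicroCluster",
    "ProceduralNetwork",
    "expand_axon",
    "extract_node_statistics",
    "fit_node_tables",
    "assign_sequence_lengths",
    "build_procedural_network",
    "materialize",
    "representation_size",
    "explicit_size",
    "ZW",
    "ZD",
    "BITS_PER_SYNAPSE",
]

ZW = 32   # weight-table bins
ZD = 64   # delay-table bins (one per 6-bit delay code)

#: bits of an explicit synapse entry: 32 (float J) + 6 (delay code) + 8 (local id)
BITS_PER_SYNAPSE = 46
#: address width of a global source id in the full-size microcircuit
SOURCE_ADDR_BITS = 17
#: per-axon seed-table entry: 32-bit seed + 16-bit L + 3-bit selector
SEED_ENTRY_BITS = 32 + 16 + 3


@dataclass(frozen=True)
class SeedTableEntry:
    """Per-source-axon procedural record: (seed, L, S)."""

    seed: int
    L: int
    S: int

    def __post_init__(self) -> None:
        if self.seed == 0:
            raise ValueError("seed 0 is not a valid xorshift state")
        if self.L < 0:
            raise ValueError("sequence length must be >= 0")


@dataclass
class NetworkRealization:
    """Explicit synapse list: columnar quadruples (delta, J, D_code, N).

    ``delta`` is the global source id, ``J`` the strength in pA
    (single precision), ``D_code`` the 6-bit delay code (delivery after
    (code + 1) * dt), and ``N_global`` the global target id.
    """

    delta: np.ndarray
    J: np.ndarray
    D_code: np.ndarray
    N_global: np.ndarray
    n_neurons: int = 0

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.J = np.asarray(self.J, dtype=np.float32)
        self.D_code = np.asarray(self.D_code, dtype=np.uint8)
        self.N_global = np.asarray(self.N_global, dtype=np.int64)
        if self.D_code.size and int(self.D_code.max()) > 63:
            raise ValueError("delay codes must fit in 6 bits")

    def __len__(self) -> int:
        return len(self.delta)

    def to_tsv(self, path) -> None:
        arr = np.column_stack([self.delta, self.D_code.astype(np.int64), self.N_global])
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={self.n_neurons}\n")
            fh.write("delta\tJ\tD_code\tN_global\n")
            for i in range(len(self)):
                fh.write(f"{arr[i,0]}\t{float(self.J[i])!r}\t{arr[i,1]}\t{arr[i,2]}\n")

    @classmethod
    def from_tsv(cls, path) -> "NetworkRealization":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# n_neurons="):
                raise ValueError("malformed synapse table: missing header")
            n_neurons = int(header.split("=")[1])
            fh.readline()  # column names
            rows = [line.split("\t") for line in fh if line.strip()]
        if not rows:
            return cls(np.empty(0, np.int64), np.empty(0, np.float32),
                       np.empty(0, np.uint8), np.empty(0, np.int64), n_neurons)
        return cls(
            delta=np.array([int(r[0]) for r in rows]),
            J=np.array([np.float32(r[1]) for r in rows], dtype=np.float32),
            D_code=np.array([int(r[2]) for r in rows], dtype=np.uint8),
            N_global=np.array([int(r[3]) for r in rows]),
            n_neurons=n_neurons,
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["n_neurons"] = self.n_neurons
            f.create_dataset("delta", data=self.delta)
            f.create_dataset("J", data=self.J)
            f.create_dataset("D_code", data=self.D_code)
            f.create_dataset("N_global", data=self.N_global)

    @classmethod
    def from_hdf5(cls, path) -> "NetworkRealization":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                delta=f["delta"][:], J=f["J"][:], D_code=f["D_code"][:],
                N_global=f["N_global"][:], n_neurons=int(f.attrs["n_neurons"]),
            )


@dataclass
class MicroCluster:
    """One compute-node's sub-network: <= 256 neurons of one population."""

    node_id: int
    pop: int
    gid_lo: int
    gid_hi: int  # exclusive

    @property
    def size(self) -> int:
        return self.gid_hi - self.gid_lo


@dataclass
class ProceduralNetwork:
    """Seed tables + fitted alias tables for a set of micro-clusters.

    Dense per-cluster arrays over all possible sources: ``L[c, delta]``
    synapse counts and ``seeds[c, delta]`` expansion seeds.  Alias
    tables are packed per (cluster, source population) for the weight
    and delay channels; target draws are uniform over the cluster size.
    """

    clusters: list
    n_sources: int
    n_pops: int
    pop_of: np.ndarray        # (n_sources,) population of each source gid
    pop_is_exc: np.ndarray    # (n_pops,) bool
    L: np.ndarray             # (n_clusters, n_sources) uint16
    seeds: np.ndarray         # (n_clusters, n_sources) uint64 (32-bit values)
    wH: np.ndarray            # (n_clusters, n_pops, ZW) uint32
    wN: np.ndarray            # float32 natural weight values
    wA: np.ndarray            # float32 alias weight values
    dH: np.ndarray            # (n_clusters, n_pops, ZD) uint32
    dN: np.ndarray            # uint8 natural delay codes
    dA: np.ndarray            # uint8 alias delay codes
    missing_selectors: set = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    # geometry arrays for the kernels
    def _geometry(self):
        lo = np.array([c.gid_lo for c in self.clusters], dtype=np.int64)
        size = np.array([c.size for c in self.clusters], dtype=np.int64)
        tbits = np.array([int(s - 1).bit_length() if s > 1 else 0 for s in size],
                         dtype=np.int64)
        return lo, size, tbits

    def total_synapses(self) -> int:
        return int(self.L.sum())

    def mtbrng_view(self, node_id: int) -> Mtbrng:
        """Pure-Python MTBRNG over this cluster's fitted tables (the
        reference path; the compiled kernels replicate it)."""
        c = node_id
        size = self.clusters[c].size
        tables = {}
        for s in range(self.n_pops):
            tables[s] = {
                "weight": AliasTable(H=self.wH[c, s].astype(np.uint64),
                                     A=self.wA[c, s], N=self.wN[c, s],
                                     semantics="weight_pA"),
                "delay": AliasTable(H=self.dH[c, s].astype(np.uint64),
                                    A=self.dA[c, s], N=self.dN[c, s],
                                    semantics="delay_code"),
                "target": AliasTable(H=np.full(size, (1 << 32) - 1, dtype=np.uint64),
                                     A=np.arange(size), N=np.arange(size),
                                     semantics="local_target"),
            }
        return Mtbrng(tables=tables)

    def seed_entry(self, node_id: int, delta: int) -> SeedTableEntry:
        return SeedTableEntry(seed=int(self.seeds[node_id, delta]),
                              L=int(self.L[node_id, delta]),
                              S=int(self.pop_of[delta]))


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

def expand_axon(entry: SeedTableEntry, mt: Mtbrng) -> list:
    """Expand one seed-table entry into its L (J, D, N) triples.

    Per synapse the draw order is fixed as target N, delay D, weight J,
    all on the two shared generator streams seeded from ``entry.seed``.
    Deterministic: expanding the same entry twice yields the same list.
    """
    if entry.S not in mt.tables:
        raise KeyError(f"missing selector {entry.S} in MTBRNG tables")
    mt.reseed(entry.seed)
    out = []
    for _ in range(entry.L):
        n, mt.index_state, mt.threshold_state = tbrng_draw(
            mt.tables[entry.S]["target"], mt.index_state, mt.threshold_state, mt.params)
        d, mt.index_state, mt.threshold_state = tbrng_draw(
            mt.tables[entry.S]["delay"], mt.index_state, mt.threshold_state, mt.params)
        j, mt.index_state, mt.threshold_state = tbrng_draw(
            mt.tables[entry.S]["weight"], mt.index_state, mt.threshold_state, mt.params)
        out.append((np.float32(j), int(d), int(n)))
    return out


# ---------------------------------------------------------------------------
# fitting from a reference realization
# ---------------------------------------------------------------------------

def _cluster_index_of_targets(ref: NetworkRealization, clusters: list) -> np.ndarray:
    """Map every synapse's target gid to its cluster id (clusters hold
    contiguous gid ranges)."""
    bounds = np.array([c.gid_lo for c in clusters] + [clusters[-1].gid_hi])
    idx = np.searchsorted(bounds, ref.N_global, side="right") - 1
    if idx.size and (idx.min() < 0 or idx.max() >= len(clusters)):
        raise ValueError("reference network contains targets outside the clusters")
    return idx


def extract_node_statistics(ref: NetworkRealization, cluster: MicroCluster,
                            pop_of: np.ndarray, n_pops: int) -> dict:
    """Empirical weight/delay/multiplicity statistics of one cluster's
    incoming synapses, partitioned by source population."""
    m = (ref.N_global >= cluster.gid_lo) & (ref.N_global < cluster.gid_hi)
    spop = pop_of[ref.delta[m]]
    stats = {}
    for s in range(n_pops):
        sm = spop == s
        w = ref.J[m][sm].astype(np.float64)
        d = ref.D_code[m][sm]
        mult = np.bincount(ref.delta[m][sm], minlength=len(pop_of))
        mult = mult[pop_of == s]
        stats[s] = {
            "count": int(sm.sum()),
            "weights": w,
            "delay_hist": np.bincount(d, minlength=ZD)[:ZD],
            "multiplicity": mult,
        }
    return stats


def fit_node_tables(stats: dict, cluster_size: int, z: int = ZW):
    """Fit per-selector alias tables from extracted statistics.

    Weights: normal fit (sample mean/sd), discretized into z
    equal-probability bins clipped at +-4 sd.  Delays: empirical
    histogram over the 64 delay codes.  Selectors with no synapses are
    omitted and flagged.  Returns (tables, missing) where tables maps
    selector -> {"weight": Pmf-backed AliasTable, "delay": ...}.
    """
    tables, missing = {}, set()
    for s, st in stats.items():
        if st["count"] == 0:
            missing.add(s)
            continue
        w = st["weights"]
        mu, sd = float(w.mean()), float(w.std(ddof=1)) if len(w) > 1 else 0.0
        if sd > 0:
            wpmf = discretize_pdf("normal", (mu, sd), z, (mu - 4 * sd, mu + 4 * sd))
        else:
            wpmf = Pmf(values=np.array([mu]), probs=np.array([1.0]))
        dpmf = pmf_from_counts(np.arange(ZD), np.maximum(st["delay_hist"], 0))
        tables[s] = {
            "weight": build_alias_table(wpmf, semantics="weight_pA"),
            "delay": build_alias_table(dpmf, semantics="delay_code"),
        }
    return tables, missing


def assign_sequence_lengths(ref: NetworkRealization, clusters: list,
                            master_seed: int):
    """Per-cluster (seed, L) arrays: L is the exact per-source synapse
    count of the reference realization; seeds derive from the master
    seed by mixing (node_id, source gid)."""
    n_clusters = len(clusters)
    n_sources = ref.n_neurons
    cidx = _cluster_index_of_targets(ref, clusters)
    flat = ref.delta * n_clusters + cidx
    counts = np.bincount(flat, minlength=n_sources * n_clusters)
    L = counts.reshape(n_sources, n_clusters).T.astype(np.uint16)
    if counts.max() > np.iinfo(np.uint16).max:
        raise OverflowError("per-cluster multiplicity exceeds 16-bit L field")
    seeds = np.empty((n_clusters, n_sources), dtype=np.uint64)
    for c in range(n_clusters):
        for d in range(n_sources):
            seeds[c, d] = derive_seed(master_seed, c, d)
    return L, seeds


def _fast_seeds(master_seed: int, n_clusters: int, n_sources: int) -> np.ndarray:
    """Vectorized equivalent of derive_seed(master, c, d) for all (c, d)."""
    M = np.uint64(0xFFFFFFFFFFFFFFFF)

    def mix(x):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & M
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & M
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & M
        return x ^ (x >> np.uint64(31))

    with np.errstate(over="ignore"):
        m = np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF)
        cs = mix(np.arange(n_clusters, dtype=np.uint64))[:, None]
        x = mix(m ^ cs)
        ds = mix(np.arange(n_sources, dtype=np.uint64))[None, :]
        x = mix(x ^ ds)
    s = x & np.uint64(0xFFFFFFFF)
    s[s == 0] = 1
    return s


def build_procedural_network(ref: NetworkRealization, clusters: list,
                             pop_of: np.ndarray, pop_is_exc: np.ndarray,
                             master_seed: int, z: int = ZW) -> ProceduralNetwork:
    """Full fitting pipeline: statistics extraction, table fitting and
    sequence-length assignment for every cluster."""
    n_clusters = len(clusters)
    n_sources = ref.n_neurons
    n_pops = len(pop_is_exc)
    cidx = _cluster_index_of_targets(ref, clusters)
    spop = pop_of[ref.delta]
    key = cidx * n_pops + spop

    # per (cluster, srcpop): counts, weight mean/sd, delay histograms
    nk = n_clusters * n_pops
    cnt = np.bincount(key, minlength=nk).astype(np.float64)
    wsum = np.bincount(key, weights=ref.J.astype(np.float64), minlength=nk)
    wsq = np.bincount(key, weights=ref.J.astype(np.float64) ** 2, minlength=nk)
    dhist = np.bincount(key * ZD + ref.D_code, minlength=nk * ZD).reshape(nk, ZD)

    wH = np.zeros((n_clusters, n_pops, z), dtype=np.uint32)
    wN = np.zeros((n_clusters, n_pops, z), dtype=np.float32)
    wA = np.zeros((n_clusters, n_pops, z), dtype=np.float32)
    dH = np.zeros((n_clusters, n_pops, ZD), dtype=np.uint32)
    dN = np.zeros((n_clusters, n_pops, ZD), dtype=np.uint8)
    dA = np.zeros((n_clusters, n_pops, ZD), dtype=np.uint8)
    missing = set()
    for c in range(n_clusters):
        for s in range(n_pops):
            k = c * n_pops + s
            n = cnt[k]
            if n == 0:
                missing.add((c, s))
                continue
            mu = wsum[k] / n
            var = max(wsq[k] / n - mu * mu, 0.0) * (n / max(n - 1, 1))
            sd = float(np.sqrt(var))
            if sd > 0:
                wpmf = discretize_pdf("normal", (mu, sd), z, (mu - 4 * sd, mu + 4 * sd))
            else:
                wpmf = Pmf(values=np.array([mu]), probs=np.array([1.0]))
            wt = build_alias_table(wpmf, semantics="weight_pA")
            zz = wt.z
            # degenerate tables have z < ZW: tile the point mass
            wH[c, s, :] = np.resize(wt.H.astype(np.uint32), z)
            wN[c, s, :] = np.resize(wt.N.astype(np.float32), z)
            wA[c, s, :] = np.resize(wt.A.astype(np.float32), z)
            if zz not in (1, z):
                raise AssertionError("unexpected weight-table size")
            dt_ = build_alias_table(pmf_from_counts(np.arange(ZD), dhist[k]),
                                    semantics="delay_code")
            dH[c, s, :] = dt_.H.astype(np.uint32)
            dN[c, s, :] = dt_.N.astype(np.uint8)
            dA[c, s, :] = dt_.A.astype(np.uint8)

    L, _ = _assign_L_only(ref, clusters, cidx)
    seeds = _fast_seeds(master_seed, n_clusters, n_sources)
    return ProceduralNetwork(
        clusters=clusters, n_sources=n_sources, n_pops=n_pops,
        pop_of=pop_of.astype(np.int64), pop_is_exc=pop_is_exc.astype(np.bool_),
        L=L, seeds=seeds, wH=wH, wN=wN, wA=wA, dH=dH, dN=dN, dA=dA,
        missing_selectors=missing,
    )


def _assign_L_only(ref: NetworkRealization, clusters: list, cidx: np.ndarray):
    n_clusters = len(clusters)
    n_sources = ref.n_neurons
    flat = ref.delta * n_clusters + cidx
    counts = np.bincount(flat, minlength=n_sources * n_clusters)
    if counts.max() > np.iinfo(np.uint16).max:
        raise OverflowError("per-cluster multiplicity exceeds 16-bit L field")
    return counts.reshape(n_sources, n_clusters).T.astype(np.uint16), counts


# ---------------------------------------------------------------------------
# materialization and size accounting
# ---------------------------------------------------------------------------

def materialize(pn: ProceduralNetwork) -> NetworkRealization:
    """Expand every seed-table axon into an explicit quadruple list.

    The result is in canonical (source, cluster, draw-index) order and
    re-expansion is bit-identical, so simulating it with the explicit
    backend reproduces the procedural backend exactly.
    """
    total = pn.total_synapses()
    out_delta = np.empty(total, dtype=np.int64)
    out_J = np.empty(total, dtype=np.float32)
    out_D = np.empty(total, dtype=np.uint8)
    out_N = np.empty(total, dtype=np.int64)
    lo, size, tbits = pn._geometry()
    n = _kernels.materialize_kernel(
        pn.L, pn.seeds, pn.pop_of, lo, size, tbits,
        pn.wH, pn.wN, pn.wA, pn.dH, pn.dN, pn.dA,
        out_delta, out_J, out_D, out_N)
    assert n == total
    n_neurons = pn.clusters[-1].gid_hi if pn.clusters else 0
    return NetworkRealization(delta=out_delta, J=out_J, D_code=out_D,
                              N_global=out_N, n_neurons=max(n_neurons, pn.n_sources))


def representation_size(pn: ProceduralNetwork) -> int:
    """Size in bits of the procedural representation: dense per-cluster
    seed tables (32-bit seed + 16-bit L + 3-bit selector per possible
    source) plus all packed alias tables."""
    seed_bits = pn.n_clusters * pn.n_sources * SEED_ENTRY_BITS
    w_bits = pn.wH.size * 32 + pn.wN.size * 32 + pn.wA.size * 32
    d_bits = pn.dH.size * 32 + pn.dN.size * 6 + pn.dA.size * 6
    return seed_bits + w_bits + d_bits


def seedtable_bits(n_clusters: int, n_sources: int, n_pops: int,
                   zw: int = ZW, zd: int = ZD) -> int:
    """Accounting-only variant of :func:`representation_size` from raw
    dimensions (used for the full-size network without building it)."""
    seed_bits = n_clusters * n_sources * SEED_ENTRY_BITS
    table_bits = n_clusters * n_pops * (zw * (32 + 32 + 32) + zd * (32 + 6 + 6))
    return seed_bits + table_bits


def explicit_size(n_synapses: int, n_active_axon_entries: int = 0) -> int:
    """Bits of the explicit list: 46 per synapse (32-bit J, 6-bit delay
    code, 8-bit local target) plus one 17-bit source address per stored
    per-axon run."""
    return n_synapses * BITS_PER_SYNAPSE + n_active_axon_entries * SOURCE_ADDR_BITS
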