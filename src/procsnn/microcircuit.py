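"""Built-in cortical microcircuit benchmark and small network fixtures.

The microcircuit represents the network under ~1 mm^2 of early sensory
cortex: four layers (L2/3, L4, L5, L6), each with an excitatory and an
inhibitory population — 77,169 LIF neurons in eight populations and
about 0.3 billion synapses, wired by population-specific pairwise
connection probabilities.  Synaptic strengths and transmission delays
are normally distributed; roughly half of each neuron's excitatory
drive is network-internal, the other half is supplied as independent
Poisson input with population-specific fan-ins at 8 spikes/s per
external source.

Also provided: a two-population balanced random network ("Brunel-style"
fixture) for desk-scale testing, and a downscaling operation.  Note
that downscaling preserves mean activity at best; second-order
statistics (correlations, fluctuations) are severely distorted, so
scaled networks serve software validation, not science.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .connectivity import NetworkRealization
from .neurons import LifParams

__all__ = [
    "PopulationSpec",
    "ConnectivitySpec",
    "ModelSpec",
    "default_microcircuit",
    "brunel_fixture",
    "scale",
    "build_reference_network",
    "expected_synapse_count",
    "full_scale_indegree_counts",
]

#: downscaling distorts correlations even when means are preserved
DOWNSCALING_CAVEAT = (
    "Downscaled network: mean first-order activity can be preserved, but "
    "second-order statistics (correlations, fluctuation structure) are not "
    "representative of the full-size model."
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    excitatory: bool
    ext_fanin: int        # M_q: number of external Poisson sources
    ext_rate: float       # lambda_q: rate per external source, spikes/s


@dataclass
class ConnectivitySpec:
    """Pairwise-Bernoulli wiring statistics.

    ``probs[t, s]`` is the connection probability from a neuron of
    source population s to a neuron of target population t.  Weights
    are normal per (s is excitatory or inhibitory), with per-block mean
    overrides in ``w_mean_override`` (the benchmark doubles the
    L4E -> L2/3E mean).  Delays are normal per source type, quantized to
    the dt grid and clipped to delay codes [0, 63].
    """

    probs: np.ndarray                  # (n_pops, n_pops), target x source
    w_exc_mean: float = 87.81          # pA (0.15 mV PSP at the LIF defaults)
    w_rel_sd: float = 0.1
    g: float = -4.0                    # inhibitory weight = g * w_exc_mean
    w_mean_override: dict = field(default_factory=dict)  # (tgt, src) -> mean pA
    delay_exc: tuple = (1.5, 0.75)     # ms (mean, sd)
    delay_inh: tuple = (0.75, 0.375)   # ms
    J_ext: float = 87.81               # pA, common external strength

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")

    def block_weight(self, tgt: int, src: int, src_exc: bool) -> tuple:
        """(mean, sd) of the weight for one population block, in pA."""
        mean = self.w_mean_override.get(
            (tgt, src), self.w_exc_mean if src_exc else self.g * self.w_exc_mean)
        return mean, abs(mean) * self.w_rel_sd


@dataclass
class ModelSpec:
    populations: list
    connectivity: ConnectivitySpec
    lif: LifParams
    dt: float = 0.1                    # ms
    scale_factor: float = 1.0
    connection_rule: str = "bernoulli"  # or "fixed_total"
    notes: list = field(default_factory=list)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.populations], dtype=np.int64)

    @property
    def n_neurons(self) -> int:
        return int(self.sizes.sum())

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def pop_is_exc(self) -> np.ndarray:
        return np.array([p.excitatory for p in self.populations], dtype=np.bool_)

    def pop_of(self) -> np.ndarray:
        """Population index of every global id (ids are assigned
        population-contiguously, 0-based)."""
        return np.repeat(np.arange(self.n_pops), self.sizes)

    def gid_ranges(self) -> list:
        offs = np.concatenate([[0], np.cumsum(self.sizes)])
        return [(int(offs[i]), int(offs[i + 1])) for i in range(self.n_pops)]

    # --- structured text round trip -------------------------------------
    def to_json(self) -> str:
        d = {
            "populations": [asdict(p) for p in self.populations],
            "connectivity": {
                "probs": self.connectivity.probs.tolist(),
                "w_exc_mean": self.connectivity.w_exc_mean,
                "w_rel_sd": self.connectivity.w_rel_sd,
                "g": self.connectivity.g,
                "w_mean_override": {f"{t},{s}": v for (t, s), v
                                    in self.connectivity.w_mean_override.items()},
                "delay_exc": list(self.connectivity.delay_exc),
                "delay_inh": list(self.connectivity.delay_inh),
                "J_ext": self.connectivity.J_ext,
            },
            "lif": asdict(self.lif),
            "dt": self.dt,
            "scale_factor": self.scale_factor,
            "connection_rule": self.connection_rule,
            "notes": self.notes,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        conn = d["connectivity"]
        return cls(
            populations=[PopulationSpec(**p) for p in d["populations"]],
            connectivity=ConnectivitySpec(
                probs=np.asarray(conn["probs"]),
                w_exc_mean=conn["w_exc_mean"], w_rel_sd=conn["w_rel_sd"],
                g=conn["g"],
                w_mean_override={tuple(map(int, k.split(","))): v
                                 for k, v in conn["w_mean_override"].items()},
                delay_exc=tuple(conn["delay_exc"]),
                delay_inh=tuple(conn["delay_inh"]), J_ext=conn["J_ext"]),
            lif=LifParams(**d["lif"]), dt=d["dt"],
            scale_factor=d["scale_factor"],
            connection_rule=d.get("connection_rule", "bernoulli"),
            notes=d.get("notes", []),
        )


# ---------------------------------------------------------------------------
# built-in parameterizations
# ---------------------------------------------------------------------------

_MC_NAMES = ["L2/3E", "L2/3I", "L4E", "L4I", "L5E", "L5I", "L6E", "L6I"]
_MC_SIZES = [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948]
_MC_EXT_FANIN = [1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100]
_MC_BG_RATE = 8.0  # spikes/s per external source

# connection probabilities, rows = target population, columns = source
_MC_PROBS = [
    [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0000, 0.0076, 0.0000],
    [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0000, 0.0042, 0.0000],
    [0.0077, 0.0059, 0.0497, 0.1350, 0.0067, 0.0003, 0.0453, 0.0000],
    [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0000, 0.1057, 0.0000],
    [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0000],
    [0.0548, 0.0269, 0.0257, 0.0022, 0.0600, 0.3158, 0.0086, 0.0000],
    [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],
    [0.0364, 0.0010, 0.0034, 0.0005, 0.0277, 0.0080, 0.0658, 0.1443],
]


def default_microcircuit() -> ModelSpec:
    """The full-size eight-population microcircuit parameterization."""
    pops = [
        PopulationSpec(name=n, size=s, excitatory=(i % 2 == 0),
                       ext_fanin=m, ext_rate=_MC_BG_RATE)
        for i, (n, s, m) in enumerate(zip(_MC_NAMES, _MC_SIZES, _MC_EXT_FANIN))
    ]
    conn = ConnectivitySpec(
        probs=np.asarray(_MC_PROBS),
        # the L4E -> L2/3E projection has twice the mean strength
        w_mean_override={(0, 2): 2 * 87.81},
    )
    return ModelSpec(populations=pops, connectivity=conn, lif=LifParams())


def brunel_fixture(N: int = 1000, p: float = 0.1, g: float = 5.0,
                   seed: int = 0, eta: float = 2.0) -> ModelSpec:
    """Two-population balanced random network (80% E / 20% I).

    External drive is set analytically at ``eta`` times the rate that
    would bring the mean membrane potential to threshold, placing the
    network in an active, inhibition-dominated regime.  Deterministic in
    its arguments; ``seed`` is recorded for provenance only.
    """
    NE, NI = int(0.8 * N), N - int(0.8 * N)
    lif = LifParams()
    w = 87.81
    CE = max(1, round(p * NE))
    # threshold drive: CE * nu_thr * J * tau_s = (V_th - E_L) * g_m, so a
    # per-source rate of eta * nu_thr puts the mean input eta times above
    # rheobase before recurrent inhibition kicks in
    nu_thr = (lif.V_th - lif.E_L) * lif.g_m / (CE * w * (lif.tau_s_e / 1000.0))
    rate = eta * nu_thr
    pops = [
        PopulationSpec("E", NE, True, ext_fanin=CE, ext_rate=rate),
        PopulationSpec("I", NI, False, ext_fanin=CE, ext_rate=rate),
    ]
    conn = ConnectivitySpec(probs=np.full((2, 2), p), g=-g, J_ext=w)
    spec = ModelSpec(populations=pops, connectivity=conn, lif=lif)
    spec.notes.append(f"brunel fixture seed={seed}")
    return spec


def scale(spec: ModelSpec, factor: float,
          preserve_mean_input: bool = True) -> ModelSpec:
    """Downscale population sizes and external fan-ins by ``factor``.

    With ``preserve_mean_input`` (default), all synaptic strengths
    (recurrent and external) are multiplied by 1/factor so that the
    mean synaptic drive per neuron is unchanged while in-degrees shrink;
    input fluctuations grow accordingly.  A caveat note is attached:
    downscaling cannot preserve second-order statistics.
    """
    if not 0 < factor <= 1:
        raise ValueError("scale factor must lie in (0, 1]")
    if factor == 1.0:
        return spec
    wf = 1.0 / factor if preserve_mean_input else 1.0
    pops = [
        PopulationSpec(p.name, max(1, round(p.size * factor)), p.excitatory,
                       max(1, round(p.ext_fanin * factor)), p.ext_rate)
        for p in spec.populations
    ]
    c = spec.connectivity
    conn = ConnectivitySpec(
        probs=c.probs.copy(),
        w_exc_mean=c.w_exc_mean * wf, w_rel_sd=c.w_rel_sd, g=c.g,
        w_mean_override={k: v * wf for k, v in c.w_mean_override.items()},
        delay_exc=c.delay_exc, delay_inh=c.delay_inh, J_ext=c.J_ext * wf,
    )
    out = ModelSpec(populations=pops, connectivity=conn, lif=spec.lif,
                    dt=spec.dt, scale_factor=spec.scale_factor * factor,
                    connection_rule=spec.connection_rule,
                    notes=list(spec.notes) + [DOWNSCALING_CAVEAT])
    warnings.warn(DOWNSCALING_CAVEAT, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# reference realization
# ---------------------------------------------------------------------------

def expected_synapse_count(spec: ModelSpec) -> float:
    """Expected number of recurrent synapses, sum over blocks of
    N_pre * N_post * p."""
    sizes = spec.sizes.astype(np.float64)
    return float((sizes[None, :] * sizes[:, None] * spec.connectivity.probs).sum())


def _quantize_delays(delays_ms: np.ndarray, dt: float) -> np.ndarray:
    """Round delays to the dt grid and clip to codes [0, 63]
    (delivery after (code + 1) * dt, spanning [dt, 64 dt])."""
    steps = np.round(delays_ms / dt).astype(np.int64)
    steps = np.clip(steps, 1, 64)
    return (steps - 1).astype(np.uint8)


def build_reference_network(spec: ModelSpec, seed: int) -> NetworkRealization:
    """Draw one explicit realization of the network.

    Pairwise Bernoulli per block by default (each ordered neuron pair is
    connected independently with the block probability; autapses
    allowed, multapses impossible under this rule).  The
    ``fixed_total`` rule instead draws round(N_pre N_post p) synapses
    with replacement (multapses possible).  Weights are normal per
    block, sign-clipped at zero; delays are normal per source type,
    grid-quantized and clipped.
    """
    rng = np.random.default_rng(seed)
    sizes = spec.sizes
    offs = np.concatenate([[0], np.cumsum(sizes)])
    is_exc = spec.pop_is_exc
    c = spec.connectivity
    deltas, Js, Ds, Ns = [], [], [], []
    for t in range(spec.n_pops):
        for s in range(spec.n_pops):
            pr = c.probs[t, s]
            if pr == 0 or sizes[t] == 0 or sizes[s] == 0:
                continue
            npairs = int(sizes[s]) * int(sizes[t])
            if spec.connection_rule == "bernoulli":
                m = rng.binomial(npairs, pr)
                flat = rng.choice(npairs, size=m, replace=False)
            elif spec.connection_rule == "fixed_total":
                m = int(round(npairs * pr))
                flat = rng.integers(0, npairs, size=m)
            else:
                raise ValueError(f"unknown connection rule {spec.connection_rule!r}")
            if m == 0:
                continue
            src = offs[s] + flat // sizes[t]
            tgt = offs[t] + flat % sizes[t]
            mean, sd = c.block_weight(t, s, bool(is_exc[s]))
            w = rng.normal(mean, sd, size=m)
            w = np.maximum(w, 0.0) if is_exc[s] else np.minimum(w, 0.0)
            dm, dsd = c.delay_exc if is_exc[s] else c.delay_inh
            d = _quantize_delays(rng.normal(dm, dsd, size=m), spec.dt)
            deltas.append(src)
            Js.append(w.astype(np.float32))
            Ds.append(d)
            Ns.append(tgt)
    if not deltas:
        return NetworkRealization(
            np.empty(0, np.int64), np.empty(0, np.float32),
            np.empty(0, np.uint8), np.empty(0, np.int64), spec.n_neurons)
    return NetworkRealization(
        delta=np.concatenate(deltas), J=np.concatenate(Js),
        D_code=np.concatenate(Ds), N_global=np.concatenate(Ns),
        n_neurons=spec.n_neurons)


def full_scale_indegree_counts(spec: ModelSpec, clusters: list, seed: int) -> np.ndarray:
    """Sample the per-(cluster, source) multiplicity matrix L of a
    Bernoulli realization without materializing the synapse list.

    Under the pairwise-Bernoulli rule, the number of synapses one source
    makes inside a cluster of size c is Binomial(c, p_block); sampling
    these directly is distributionally exact and makes full-size
    representation accounting feasible in memory.
    """
    rng = np.random.default_rng(seed)
    pop_of = spec.pop_of()
    n_sources = spec.n_neurons
    L = np.zeros((len(clusters), n_sources), dtype=np.int32)
    probs = spec.connectivity.probs
    for ci, cl in enumerate(clusters):
        p_row = probs[cl.pop]           # per source population
        p_per_source = p_row[pop_of]    # (n_sources,)
        L[ci] = rng.binomial(cl.size, p_per_source)
    return L
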