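"""Bit-exact pseudo-random number generation primitives.

This module provides the three building blocks that the procedural
connectivity scheme rests on:

* **xorshift generators** -- three-shift/xor marsaglia-style PRNGs whose
  whole state is a single machine word.  A stored 32-bit seed therefore
  *is* a compressed representation of the entire pseudo-random sequence
  it generates, which is the property the seed-table network
  representation exploits.
* **alias tables** (Walker's method) -- O(1) samplers for arbitrary
  discrete probability mass functions, realized as three parallel arrays
  ``(H, A, N)`` of thresholds, alias values and natural values.
* **table-based RNGs** (TBRNG) and their multidimensional variant
  (MTBRNG), which compose two independent xorshift streams with one
  alias table (or a selector-indexed family of tables) to draw values
  with a programmed pmf.

All arithmetic is integer-exact: thresholds are stored as unsigned
32-bit fixed-point fractions and compared against raw generator words,
so a sequence is a pure function of (seed, parameters, table contents)
on every platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as _st

__all__ = [
    "XorshiftParams",
    "XorshiftState",
    "Pmf",
    "AliasTable",
    "Mtbrng",
    "DEFAULT_XORSHIFT",
    "xorshift_next",
    "uniform_index",
    "uniform_unit",
    "build_alias_table",
    "tbrng_draw",
    "mtbrng_draw",
    "discretize_pdf",
    "alias_expected_pmf",
    "derive_seed",
    "splitmix64",
]

_U32 = 1 << 32


# ---------------------------------------------------------------------------
# xorshift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class XorshiftParams:
    """Shift triple (a, b, c) and word size of a xorshift generator.

    The default triple (13, 17, 5) at width 32 is a published
    maximal-period parameterization: the orbit of any nonzero seed
    visits all 2**32 - 1 nonzero states.
    """

    a: int = 13
    b: int = 17
    c: int = 5
    width: int = 32

    def __post_init__(self) -> None:
        for s in (self.a, self.b, self.c):
            if not 0 < s < self.width:
                raise ValueError(f"shift amounts must lie in (0, {self.width})")

    @property
    def mask(self) -> int:
        return (1 << self.width) - 1


DEFAULT_XORSHIFT = XorshiftParams()


@dataclass
class XorshiftState:
    """Single-word generator state.  Zero is the fixed point of the map
    and therefore never a valid state."""

    x: int

    def __post_init__(self) -> None:
        if self.x == 0:
            raise ValueError("xorshift state 0 is invalid (fixed point)")


def xorshift_next(state: XorshiftState, params: XorshiftParams = DEFAULT_XORSHIFT):
    """Advance the generator one step: ``x ^= x<<a; x ^= x>>b; x ^= x<<c``.

    Returns ``(value, new_state)`` where ``value`` equals the new state
    word.  The update is a single self-contained call.
    """
    if state.x == 0:
        raise ValueError("xorshift state 0 is invalid (fixed point)")
    m = params.mask
    x = state.x & m
    x ^= (x << params.a) & m
    x ^= x >> params.b
    x ^= (x << params.c) & m
    return x, XorshiftState(x)


def uniform_index(state: XorshiftState, params: XorshiftParams, z: int):
    """Draw an index k uniform on [0, z) from the top bits of the stream.

    Uses the top ceil(log2 z) bits of each draw and rejects values >= z,
    which is unbiased for every z >= 1.  For powers of two no rejection
    ever occurs.  Returns ``(k, new_state)``.
    """
    if z < 1:
        raise ValueError("table size z must be >= 1")
    if z == 1:
        return 0, state
    nbits = int(z - 1).bit_length()
    shift = params.width - nbits
    while True:
        v, state = xorshift_next(state, params)
        k = v >> shift
        if k < z:
            return k, state


def uniform_unit(state: XorshiftState, params: XorshiftParams = DEFAULT_XORSHIFT):
    """Draw a fixed-point fraction h in [0, 1).

    The raw word is interpreted as h = draw / 2**width; callers that
    compare h against stored thresholds do so on the raw integers, which
    keeps every comparison exact.  Returns ``(h_int, new_state)`` with
    ``h_int`` the raw integer numerator.
    """
    v, state = xorshift_next(state, params)
    return v, state


# ---------------------------------------------------------------------------
# pmfs and alias tables
# ---------------------------------------------------------------------------

@dataclass
class Pmf:
    """Discrete pmf over representative values.

    ``values`` carries the representative output R(r) of each integer
    code r (e.g. a synaptic weight in pA, or a delay code in steps);
    ``probs`` the probability of each.  Continuous distributions are
    admitted by binning (see :func:`discretize_pdf`), each bin being
    represented by its conditional mean.
    """

    values: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.values.shape != self.probs.shape or self.values.ndim != 1:
            raise ValueError("values and probs must be 1-d arrays of equal length")
        if np.any(self.probs < 0):
            raise ValueError("pmf probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("pmf probabilities must sum to 1")
        self.probs = self.probs / self.probs.sum()

    @property
    def z(self) -> int:
        return len(self.probs)

    def mean(self) -> float:
        return float(np.dot(self.values.astype(np.float64), self.probs))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((self.values.astype(np.float64) - m) ** 2, self.probs))


@dataclass
class AliasTable:
    """Walker alias table (H, A, N) realizing a discrete pmf with O(1) draws.

    ``H`` holds 32-bit fixed-point acceptance thresholds (units of
    2**-32); ``N`` the natural value of each slot and ``A`` its alias.
    A draw picks a uniform slot k and a uniform fraction h, returning
    N(k) if h < H(k) and A(k) otherwise.  Slots whose threshold rounds
    to one store A(k) = N(k) so that point masses are sampled exactly.
    """

    H: np.ndarray           # uint32 thresholds, units of 2**-32
    A: np.ndarray           # alias values
    N: np.ndarray           # natural values
    semantics: str = "value"  # tag describing what the values mean

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.uint64)  # hold 2**32 exactly
        self.A = np.asarray(self.A)
        self.N = np.asarray(self.N)
        if not (len(self.H) == len(self.A) == len(self.N)):
            raise ValueError("H, A, N must have equal length")

    @property
    def z(self) -> int:
        return len(self.H)

    def to_json(self) -> str:
        return json.dumps(
            {
                "z": self.z,
                "H": [int(h) for h in self.H],
                "A": self.A.tolist(),
                "N": self.N.tolist(),
                "semantics": self.semantics,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "AliasTable":
        d = json.loads(s)
        return cls(
            H=np.asarray(d["H"], dtype=np.uint64),
            A=np.asarray(d["A"]),
            N=np.asarray(d["N"]),
            semantics=d.get("semantics", "value"),
        )

    def nbits(self, value_bits: int = 32) -> int:
        """Serialized size in bits: 32 per threshold plus value_bits per
        alias and natural entry."""
        return self.z * (32 + 2 * value_bits)


def build_alias_table(pmf: Pmf, semantics: str = "value") -> AliasTable:
    """Construct (H, A, N) from a pmf by Vose's O(z) algorithm.

    The expected sampling distribution (marginalizing the uniform slot k
    and the uniform 32-bit fraction h) reproduces the programmed pmf up
    to fixed-point quantization, with total-variation error <= z * 2**-32.
    """
    z = pmf.z
    scaled = pmf.probs * z            # in [0, z], sums to z
    H = np.zeros(z, dtype=np.uint64)
    A = np.empty(z, dtype=pmf.values.dtype)
    N = pmf.values.copy()
    small = [k for k in range(z) if scaled[k] < 1.0]
    large = [k for k in range(z) if scaled[k] >= 1.0]
    scaled = scaled.copy()
    while small and large:
        s = small.pop()
        g = large.pop()
        H[s] = min(int(round(scaled[s] * _U32)), _U32 - 1)
        A[s] = pmf.values[g]
        scaled[g] = (scaled[g] + scaled[s]) - 1.0
        (small if scaled[g] < 1.0 else large).append(g)
    for k in large + small:           # leftovers have threshold 1 up to fp error
        H[k] = _U32 - 1
        A[k] = pmf.values[k]          # both branches agree: exact point mass
    return AliasTable(H=H, A=A, N=N, semantics=semantics)


def alias_expected_pmf(table: AliasTable) -> dict:
    """Exact expected sampling pmf of an alias table.

    Marginalizes the uniform slot index and all 2**32 fixed-point
    fractions analytically: P(r) = sum_k [H_k 1(N_k = r) +
    (2**32 - H_k) 1(A_k = r)] / (z 2**32).  Integer-exact; serves as the
    correctness oracle for table construction.
    """
    z = table.z
    acc: dict = {}
    for k in range(z):
        h = int(table.H[k])
        # slots built with A == N saturate H at 2**32 - 1; fold the
        # missing 2**-32 back so that the marginal is exact
        if table.A[k] == table.N[k]:
            h = _U32
        nk = table.N[k].item() if hasattr(table.N[k], "item") else table.N[k]
        ak = table.A[k].item() if hasattr(table.A[k], "item") else table.A[k]
        acc[nk] = acc.get(nk, 0) + h
        acc[ak] = acc.get(ak, 0) + (_U32 - h)
    return {r: c / (z * _U32) for r, c in acc.items() if c > 0}


def tbrng_draw(table: AliasTable, index_state: XorshiftState,
               threshold_state: XorshiftState,
               params: XorshiftParams = DEFAULT_XORSHIFT):
    """One table-based draw: slot from the index stream, acceptance from
    the threshold stream; strict ``h < H(k)`` selects the natural value.

    Returns ``(value, index_state', threshold_state')``.
    """
    k, index_state = uniform_index(index_state, params, table.z)
    h, threshold_state = uniform_unit(threshold_state, params)
    value = table.N[k] if h < int(table.H[k]) else table.A[k]
    return value, index_state, threshold_state


@dataclass
class Mtbrng:
    """Multidimensional TBRNG: a selector S picks one (H, A, N) table set.

    One table set per selector holds a ``weight``, ``delay`` and
    ``target`` table; the two xorshift streams are shared across all
    channels, so the draw sequence interleaves deterministically.
    """

    tables: Mapping[object, Mapping[str, AliasTable]]
    index_state: XorshiftState = field(default_factory=lambda: XorshiftState(1))
    threshold_state: XorshiftState = field(default_factory=lambda: XorshiftState(2))
    params: XorshiftParams = DEFAULT_XORSHIFT

    def reseed(self, seed: int) -> None:
        """Initialize both streams from one 32-bit seed (see derive_seed)."""
        self.index_state = XorshiftState(seed)
        self.threshold_state = XorshiftState(scramble_seed(seed))


def mtbrng_draw(mt: Mtbrng, S, channel: str):
    """Draw one value from the (S, channel) table on the shared streams."""
    if S not in mt.tables:
        raise KeyError(f"unknown selector {S!r}")
    table = mt.tables[S][channel]
    value, mt.index_state, mt.threshold_state = tbrng_draw(
        table, mt.index_state, mt.threshold_state, mt.params
    )
    return value


# ---------------------------------------------------------------------------
# seed derivation
# ---------------------------------------------------------------------------

def splitmix64(x: int) -> int:
    """SplitMix64 finalizer; used to mix structured keys into seeds."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def derive_seed(master: int, *keys: int) -> int:
    """Derive a nonzero 32-bit xorshift seed from a master seed and a
    tuple of integer keys (e.g. (node_id, source_gid)).  Deterministic,
    well mixed, and never zero."""
    x = master & 0xFFFFFFFFFFFFFFFF
    for k in keys:
        x = splitmix64(x ^ splitmix64(k & 0xFFFFFFFFFFFFFFFF))
    s = x & 0xFFFFFFFF
    return s if s != 0 else 1


def scramble_seed(seed: int) -> int:
    """Second-stream seed derived from the stored per-axon seed so that
    the index and threshold streams are decorrelated."""
    s = splitmix64(seed) & 0xFFFFFFFF
    return s if s != 0 else 1


# ---------------------------------------------------------------------------
# continuous-distribution discretization
# ---------------------------------------------------------------------------

def discretize_pdf(dist: str, params: tuple, z: int, clip: tuple) -> Pmf:
    """Bin a continuous distribution into an equal-probability pmf.

    Parameters
    ----------
    dist : {"normal", "lognormal", "point"}
        Distribution family.  ``normal`` takes (mu, sigma); ``lognormal``
        the (mu, sigma) of the underlying normal; ``point`` a single
        value.
    z : int
        Number of bins (>= 1).
    clip : (lo, hi)
        Support truncation; bins partition [lo, hi] into intervals of
        equal conditional probability, each represented by its
        conditional mean.
    """
    lo, hi = clip
    if lo >= hi:
        raise ValueError("clip interval must satisfy lo < hi")
    if z < 1:
        raise ValueError("z must be >= 1")
    if dist == "point":
        (v,) = params
        return Pmf(values=np.array([float(np.clip(v, lo, hi))]), probs=np.array([1.0]))
    if dist == "normal":
        mu, sigma = params
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if sigma == 0:
            return Pmf(values=np.array([float(np.clip(mu, lo, hi))]), probs=np.array([1.0]))
        d = _st.norm(mu, sigma)
    elif dist == "lognormal":
        mu, sigma = params
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        d = _st.lognorm(s=sigma, scale=np.exp(mu))
    else:
        raise ValueError(f"unknown distribution family {dist!r}")

    Flo, Fhi = d.cdf(lo), d.cdf(hi)
    if Fhi - Flo <= 0:
        raise ValueError("clip interval has zero probability mass")
    qs = Flo + (Fhi - Flo) * np.linspace(0.0, 1.0, z + 1)
    edges = d.ppf(qs)
    edges[0], edges[-1] = lo, hi
    # conditional mean per bin via E[X; a<X<b] = integral of x f(x)
    reps = np.empty(z)
    for i in range(z):
        a, b = edges[i], edges[i + 1]
        mass = d.cdf(b) - d.cdf(a)
        if mass <= 0:
            reps[i] = 0.5 * (a + b)
            continue
        reps[i] = _partial_mean(dist, params, a, b) / mass
    probs = np.full(z, 1.0 / z)
    return Pmf(values=reps, probs=probs)


def _partial_mean(dist: str, params: tuple, a: float, b: float) -> float:
    """E[X; a < X < b] in closed form for the supported families."""
    if dist == "normal":
        mu, sigma = params
        al, be = (a - mu) / sigma, (b - mu) / sigma
        phi = _st.norm.pdf
        Phi = _st.norm.cdf
        return mu * (Phi(be) - Phi(al)) + sigma * (phi(al) - phi(be))
    if dist == "lognormal":
        mu, sigma = params
        al = (np.log(a) - mu) / sigma if a > 0 else -np.inf
        be = (np.log(b) - mu) / sigma if b > 0 else -np.inf
        Phi = _st.norm.cdf
        return float(np.exp(mu + 0.5 * sigma**2) * (Phi(be - sigma) - Phi(al - sigma)))
    raise ValueError(dist)


def pmf_from_counts(values: Iterable, counts: Iterable, semantics: str = "value") -> Pmf:
    """Empirical pmf from a histogram (used for delay-code tables)."""
    counts = np.asarray(list(counts), dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    return Pmf(values=np.asarray(list(values)), probs=counts / total)
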