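# Methods

## The model

`procsnn` simulates networks of leaky integrate-and-fire (LIF) neurons
with lumped, current-based (CUBA) synapses on a fixed time grid of
Δt = 0.1 ms:

    C_m dV_q/dt = −g_m (V_q − E_L) + I_e,q + I_i,q + I_ext
    τ_s,x dI_x,q/dt = −I_x,q + I_S,x,q(t),           x ∈ {e, i}

Each neuron carries one excitatory and one inhibitory synaptic state
into which all same-type inputs are summed; a presynaptic spike of
weight J arriving with delay D adds J to the corresponding state
(exponential kernel) D steps after emission.  When V_q crosses V_th
the neuron emits a spike, V_q is reset, and the membrane is clamped at
V_reset for the refractory period t_ref while the synaptic states keep
evolving (the convention of mainstream LIF simulators).  All simulation
state is held in 32-bit floats; the update constants are precomputed in
double precision and cast once.

The benchmark parameterization is the eight-population cortical
microcircuit (L2/3E/I, L4E/I, L5E/I, L6E/I; 77,169 neurons; ≈0.3·10⁹
synapses at population-specific pairwise connection probabilities).
Neuron constants: C_m = 250 pF, τ_m = 10 ms, E_L = V_reset = −65 mV,
V_th = −50 mV, t_ref = 2 ms, τ_s = 0.5 ms.  Excitatory weights are
normal with mean 87.81 pA (a 0.15 mV PSP) and 10% relative sd, the
L4E→L2/3E mean doubled; inhibitory weights have g = −4 times the
excitatory mean.  Delays are normal (1.5 ± 0.75 ms excitatory,
0.75 ± 0.375 ms inhibitory), rounded to the grid and clipped to
1..64 steps.  Every neuron additionally receives independent Poisson
drive from M_q external sources at 8 spikes/s each with the common
strength 87.81 pA.

## Exact integration

The subthreshold system is linear, so one step is advanced error-free
by the matrix exponential of the system matrix: P = exp(M Δt), applied
as y ← P (y − y*) + y* with y* the fixed point under the constant
external current.  P is upper triangular in the state ordering
[V, I_e, I_i] (or [V, I_e, Z_e, I_i, Z_i] for the α/β kernels); the
3-state entries are assembled in closed form, with the analytic limit
t e^{−t/τ} when two time constants coincide (tested against a numeric
matrix exponential to 1e-12), and the 5-state propagator is evaluated
directly as a double-precision matrix exponential.  α/β kernels are
peak-normalized: a weight-J spike jumps the auxiliary state by the
factor that makes the resulting current peak exactly J; α is the
equal-rise/decay limit of β.

## Solver suite

For nonlinear neuron models the package provides classical Runge-Kutta
steps of order 1, 2 and 4 (one step per grid interval, no sub-stepping)
and Parker-Sochacki integration of orders 1–6, which computes the exact
Maclaurin coefficients of the solution by recurrences on the
right-hand side: polynomial terms via Cauchy products (the Izhikevich
quadratic, COBA products g·V), and the AdEx exponential through an
auxiliary series E = exp((V−V_T)/Δ_T) propagated by E' = E·V'/Δ_T.
PS-1 reduces exactly to forward Euler; PS-4 and RK4 share the
fourth-order Taylor polynomial, so their one-step difference is
O(Δt⁵).  Observed global-error convergence orders on the linear test
system match the nominal orders (log-log slopes within 0.2).  The
network engine itself always uses exact integration — the benchmark's
model is linear; the nonlinear models and solvers are library-level
components with their own tests.

## Procedural connectivity

The synapse table is replaced by per-axon pseudo-random seeds.  The
target neurons are partitioned into population-pure micro-clusters of
at most 256 neurons (the full model maps to 305).  Per cluster and per
possible source axon δ, a seed-table entry (seed, L, S) stores a
32-bit xorshift seed, the number L of synapses that axon makes in the
cluster, and the selector S (the source's population).  When δ spikes,
every cluster reseeds its table-based generators and draws exactly L
(target, delay, weight) triples in the fixed order N, D, J; because the
generators are deterministic, every expansion of an axon yields the
same synapses, so the network never needs to be stored explicitly.

The generators are Walker alias tables (H, A, N) driven by two shared
xorshift32 streams (triple (13, 17, 5), a maximal-period
parameterization): one stream supplies the slot index (top ⌈log₂ z⌉
bits, rejection-resampled for non-power-of-two z — unbiased), the other
a 32-bit fixed-point fraction compared against H(k); strict h < H(k)
selects the natural value.  Thresholds are stored as unsigned 32-bit
integers and all comparisons are integer-exact, so sequences are
reproducible bit for bit across platforms.  The exact expected pmf of
a constructed table (marginalizing slot and fraction analytically)
matches the programmed pmf within total variation z·2⁻³².

Tables are fitted from a reference realization: per (cluster, source
population), weights are fitted as a normal and discretized into 32
equal-probability bins clipped at ±4 sd (each bin represented by its
conditional mean), the delay-code distribution is carried over as an
empirical 64-bin histogram, and targets are uniform over the cluster.
L is the exact per-source synapse count of the reference realization,
so the synapse count and the multiplicity distribution are conserved
exactly; weights and delays are preserved in distribution (total
variation ≲ 1% at 10⁵ synapses per table set).  Per-axon seeds derive
from a 64-bit master seed by SplitMix64 mixing of (cluster, source);
the threshold stream reseeds from a scrambled copy of the stored seed.

Size accounting uses 46 bits per explicit synapse (32-bit float weight,
6-bit delay code, 8-bit local target) plus a 17-bit source address per
stored axon run, against 51 bits per dense seed-table entry
(32 + 16 + 3) plus the alias tables; on the full-size mapping the
seed-table representation is ≈11× smaller.

## Simulation loop

Per step, in fixed order: the 64-slot circular delay buffer's current
slot is read and cleared (so a maximum-delay write lands safely in the
just-cleared slot); external input is drawn; the propagator advances
all neurons; threshold crossings are collected with ties broken by
ascending global id; every spike is routed into future buffer slots at
(t + D + 1) mod 64 — same-step delivery is impossible, matching the
one-step minimum delay.  All spikes of step t are visible to every
cluster before step t + 1.  External drive per neuron and step is a
count drawn from a 32-entry alias table programmed with
Poisson(M_q Δt λ_q) truncated at 31 and renormalized (truncated mass
< 10⁻²⁰ at benchmark parameters), multiplied by J_q; an alternative
mode folds the multiplication into the table values.  The external
streams, the per-axon expansion streams and the initial-state draws
are independent, deterministically derived streams, so the procedural
and explicit backends — and repeated runs — produce bit-identical spike
records for the same master seed.

Hot loops (axon expansion, spike delivery) are numba-compiled replicas
of the pure-Python generator semantics; the test suite asserts
synapse-for-synapse equality of the two paths.

## Validation statistics

Three measures, computed strictly after a 1,000 ms transient cut:
firing rate n_sp/T per neuron; the coefficient of variation of the
inter-spike intervals (sample sd with n−1 denominator over the mean;
neurons with fewer than 3 spikes excluded, exclusion counts reported);
and pairwise Pearson correlations of spike trains binned at 2 ms,
pooled over neuron pairs, computed on a deterministic subsample of 100
neurons per population (the pair count is quadratic) with zero-variance
trains excluded.  The Pearson normalization is the standard symmetric
one, √(⟨b_i−μ_i⟩²⟨b_j−μ_j⟩²).  Two simulations are compared by the
two-sample Kolmogorov-Smirnov statistic of each measure's distribution
plus a histogram-overlap coefficient; the operational pass criterion is
KS ≤ 0.1, a documented package choice — no canonical equivalence test
exists for this comparison.

## Downscaling

`scale(spec, k)` shrinks population sizes and external fan-ins by k.
By default it also multiplies all synaptic strengths by 1/k, which
preserves every neuron's *mean* input exactly while in-degrees drop —
without this the scaled network's drive falls an order of magnitude
short of threshold and the dynamics collapse to silence.  Input
*fluctuations* grow as 1/√k, so second-order statistics (correlations,
fluctuation structure) are not representative of the full-size model;
a caveat is attached to every scaled spec, and the uncompensated
variant is available (`preserve_mean_input=False`).  Desk-scale runs
therefore validate the software (backend equivalence, seed-to-seed
distributional stability), not full-scale neuroscience.

## Problem sizes and numerical choices

Tests and the acceptance script exercise: the full-size model for
construction and size accounting only (the per-cluster multiplicity
matrix is sampled directly as binomials, which is distributionally
exact under Bernoulli wiring and avoids materializing 0.3·10⁹
synapses); a 10%-scaled microcircuit (7,717 neurons, ≈2.85·10⁶
synapses) for dynamics — 10 s of biological time per seed for the
two-seed distribution comparison, 1 s for backend equivalence; and a
1,000-neuron balanced random network.  The balanced-network fixture
sets its external rate analytically at twice the rheobase rate, giving
an active inhibition-dominated regime with CV ≈ 1.

Degenerate inputs: zero-probability pmf entries are legal (their alias
slots are never selected); an all-equal weight sample collapses to a
single-value table; clusters of size one consume no index draw, but
every TBRNG draw always consumes exactly one threshold draw, keeping
stream alignment independent of table content.  Initial membrane
potentials are drawn N(−58, 10) mV and clipped just below threshold to
avoid a synchronous step-0 volley.  Pmf normalization is enforced to
1e-9 (float64 accumulation over 64 quantile bins).

## Known limitations

- Synaptic plasticity is out of scope; the representation is static.
- The engine's network dynamics are LIF + CUBA-exponential only; the
  nonlinear models and the α/β kernels are solver-level components.
- Bernoulli wiring is the default; the fixed-total-number variant is
  provided but the benchmark's original supplementary convention may
  differ in autapse/multapse policy (ours: autapses allowed, multapses
  arise naturally from independent target draws during expansion).
- Multi-process distribution is not implemented; correctness is defined
  by the sequential barrier semantics.
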