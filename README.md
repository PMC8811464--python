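# procsnn

Spiking-network simulation with **procedural connectivity**: instead of
storing hundreds of millions of synapses in tables, the network is
represented by per-axon PRNG seeds, and every cluster of target neurons
re-generates an axon's local synapses — targets, delays, weights —
deterministically, on the fly, each time that axon spikes.

The package is aimed at computational neuroscientists and simulator
developers who want to study this representation in software: how much
a random network compresses when encoded as seed tables, whether the
regenerated connectivity preserves the wiring statistics, and whether
the resulting network dynamics are statistically indistinguishable
from a conventionally stored network.

## What's inside

- **Bit-exact table-based RNGs** — xorshift32 generators and Walker
  alias tables `(H, A, N)` with 32-bit fixed-point thresholds; a draw
  picks a uniform slot k and returns `N(k)` if `h < H(k)` else `A(k)`,
  O(1) per sample for any discrete pmf.  A multidimensional variant
  selects the table set by the source population.
- **Seed-table networks** — per micro-cluster (≤ 256 neurons, one
  population) and per source axon δ, a triple (seed, L, S): expanding
  it yields exactly L `(N, D, J)` synapses, reproducibly.  Tables are
  fitted from a reference realization (weights: discretized normal fit;
  delays: empirical 64-code histogram; multiplicities: exact counts).
- **Solvers** — exact exponential integration for the linear LIF
  system, `V' = (−g_m(V−E_L) + I_e + I_i + I_ext)/C_m`,
  `τ_s I_x' = −I_x`, advanced by the upper-triangular propagator
  `P = exp(MΔt)`; Runge-Kutta 1/2/4 and Parker-Sochacki orders 1–6 for
  Izhikevich, AdEx and conductance-based (COBA) models.
- **Time-driven engine** — 64-slot circular delay buffers (delays
  0.1–6.4 ms at Δt = 0.1 ms), table-generated external Poisson drive
  capped at 31 spikes/neuron/step, and two interchangeable backends:
  procedural expansion vs an explicit materialized synapse list, which
  produce *bit-identical* spike records.
- **The cortical microcircuit benchmark** — the built-in eight-population
  model (L2/3, L4, L5, L6 × E/I; 77,169 neurons, ≈0.3 billion synapses,
  305 micro-clusters), plus a balanced-random-network fixture and a
  downscaling operation.
- **Validation statistics** — firing rate, CV of inter-spike intervals,
  pairwise Pearson correlations on 2-ms-binned trains, and
  distribution-level comparison (two-sample KS + overlap) between runs.

## Worked example

Build a 10%-scaled microcircuit, simulate 5 s, and summarize:

```
$ procsnn build --model microcircuit --scale-factor 0.1 --seed 1 --out-dir net
neurons: 7717
micro-clusters: 35
synapses: 2844440
seed-table representation: 1.84 MiB
explicit representation:   16.09 MiB
compression factor: 8.75

$ procsnn run --network net --duration 5000 --seed 7 --out spikes.tsv
252851 spikes -> spikes.tsv

$ procsnn validate --spikes spikes.tsv --out report.json
{
  "L2/3E": {
    "fr_mean": 2.352935999415459,
    "cv_mean": 1.0442916937648936,
    "cc_mean": 0.001248105647318033,
    "n_neurons": 2068,
    ...
```

The build step draws one explicit reference realization (2.84 M
synapses), fits the per-cluster alias tables, and reports that the
seed-table encoding is 8.75× smaller than the explicit 46-bit-per-synapse
list.  The run regenerates every axon's synapses procedurally at each
spike; the per-population summary shows the expected asynchronous
irregular regime — low rates in L2/3E, higher in L5, CV of ISI near 1,
and near-zero mean pairwise correlations.  (Statistics are computed
after discarding the first 1,000 ms; `n_cv_excluded` counts neurons
with fewer than 3 spikes in the window.)

Two runs that differ only in backend are bit-identical:

```
$ procsnn run --network net --duration 5000 --seed 7 --backend explicit --out spikes2.tsv
$ procsnn compare spikes.tsv spikes2.tsv --out cmp.json
PASS: fr KS=0.000, cv KS=0.000, cc KS=0.000
```

The same library surface is available in Python
(`procsnn.build_reference_network`, `build_procedural_network`,
`materialize`, `run`, `population_measures`, ...).

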