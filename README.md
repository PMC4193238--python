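# sparsesim

Memory-scaling theory and sparse connection/node data structures for
distributed spiking-network simulators, with a desk-scale reference
simulator of the balanced random benchmark network.

Time-driven simulators distribute a network of `N` integrate-and-fire
neurons (each receiving `K ≈ 10⁴` synapses) over `M·T` virtual processes
(VPs).  Synapses are stored on the VP of their target neuron, so each source
neuron owns a *target list* per VP.  On petascale machines `K/(MT) ≪ 1` and
almost every target list is empty or holds a single synapse:

    p_∅ = (1 − 1/N)^K_VP ,   p_1 = (1 − 1/N)^(K_VP−1)·K_VP/N ,
    K_VP = N·K/(M·T) ,

so the memory of a simulation is dominated not by synapses but by per-source
infrastructure.  `sparsesim` implements, as testable Python:

* **combinatorics** — the closed-form distribution of target-list lengths,
  its Poisson limit, and the network size `N_ζ` at which a fraction `ζ` of
  lists is non-empty (Lambert-W / bisection inversion of
  `ζ·K_VP = (1 − e^(−K_VP/N))·N`);
* **memory_model** — the per-process prediction
  `M(M,T,N,K) = M₀(M) + M_n(M,N) + M_c(M,T,N,K)` with published byte-cost
  tables for the classic ("3g") and condensed ("4g") kernel generations, and
  a maximum-filling solver (the "dry run": the largest `N` that fits a
  memory budget);
* **object_layout** — an alignment-aware struct calculator reproducing the
  condensed synapse footprints (16 B static / 24 B plastic vs the classic
  32 B) and the 4-byte packed delay+synapse-type word;
* **connection_store** — executable semantics of the adaptive per-VP
  containers: a bit-per-GID presence table, fixed-size homogeneous storage
  up to `K_cutoff = 3` records, growable promotion, heterogeneous wrapping,
  and the polymorphism-free connection handshake;
* **sparse_node_array** — ordered local-node storage with round-robin rank
  assignment (`rank = gid mod M`) and linear-interpolation GID lookup at
  16 B overhead per *local* node;
* **simulator / benchmark** — a clock-driven reference simulator (exact
  integration of LIF neurons with alpha-shaped currents, Poisson drive,
  static + power-law STDP synapses, delay-interval spike exchange across
  emulated VPs) and builders for the two benchmark parameter sets.

See `docs/methods.md` for model details, conventions, and limitations.

## Worked example

Predict the per-process memory of the record-scale configuration — the full
K computer (`M = 82,944` processes, `T = 8` threads) with parameter set 2
(`K = 6000`) at `N = 1.86·10⁹` neurons:

```sh
$ sparsesim predict-memory --generation 4g -M 82944 -T 8 -N 1.86e9 -K 6000
```

| component        | prediction |
|------------------|-----------:|
| base             |  0.262 GiB |
| buffer           |  0.309 GiB |
| sparse_table     |  4.619 GiB |
| infra_singleton  |  2.980 GiB |
| infra_multi      |  0.072 GiB |
| synapses_static  |  0.722 GiB |
| synapses_stdp    |  1.925 GiB |
| neuron_objects   |  0.023 GiB |
| neuron_infra     |  0.001 GiB |
| **total**        | **10.912 GiB** |

Of the 13.81 GiB usable per node, the prediction is dominated by the
presence table (a bit-array over all 1.86·10⁹ neurons replicated on each of
8 threads) and by the 24 B singleton-list containers — not by the synapse
objects themselves.  That inversion of the naive expectation is the central
point of the sparse-limit analysis.  The model charges theoretical object
sizes, so it underestimates a real allocator's footprint: the corresponding
maximum-filling solution (`sparsesim max-network -M 82944 -T 8 --set 2`)
returns `N_max ≈ 2.38·10⁹`, above the `1.86·10⁹` actually achieved on that
machine, with the gap in the direction and magnitude the theory predicts.

Simulate a scaled-down set-2 network and write a spike raster:

```sh
$ sparsesim simulate --set 2 -N 6000 --duration 1000 --seed 1 --gdf spikes.gdf
{
  ...
  "mean_rate_hz": 3.189,
  "n_spikes": 19136,
  ...
}
```

`spikes.gdf` is plain text, one `gid time_ms` pair per line.  The mean rate
of the dense desk-scale network sits below the machine-scale figure of
4.5 spikes/s — see the methods note on what reduced-size dynamics do and do
not show.

Other subcommands: `layout` (synapse record byte layout), `fill-fraction`
(`N_ζ` solvers), `verify-combinatorics` (empirical vs closed-form list
census), `verify-lookup` (node-array search-step statistics).

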