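# Methods

`sparsesim` re-creates, at desk scale, the memory-scaling theory and the
sparse connection/node data structures that let time-driven spiking-network
simulators use the full memory of massively parallel machines, together with
a reference simulator of the balanced random network used to benchmark them.
This note documents the models, the numerical choices, and what the shipped
tests do and do not demonstrate.

## Target-list combinatorics

A network of `N` neurons with mean in-degree `K` is distributed over
`MT` virtual processes (VPs, one per thread); synapses live on the VP of the
post-synaptic neuron.  The connectivity law throughout the package is that
every one of the `K_VP = N·K/(MT)` VP-local synapses draws its source
independently and uniformly from all `N` neurons, with replacement (multapses
and autapses allowed).  The number of VP-local targets of one source is then
binomial, giving

    p_∅ = (1 − 1/N)^K_VP
    p_1 = (1 − 1/N)^(K_VP−1) · K_VP / N
    p_>1 = 1 − p_∅ − p_1,

with Poisson limits `exp(−K/MT)` and `exp(−K/MT)·K/MT` on large machines.
`K` is a real number in the model (a mean); for fractional `K_VP < 1` the
binomial singleton expression exceeds the available mass and is capped at
`1 − p_∅` so the three probabilities always sum to one.

The network size `N_ζ` at which a fraction `ζ` of the maximal number of
non-empty lists `K_VP` is reached solves `ζ·K_VP = (1 − e^(−K_VP/N))·N`.
Three solvers are provided: root bracketing (`brentq`, the reference),
the closed form `N = −K_VP/s` with `s = −1/ζ − W0(−e^(−1/ζ)/ζ)` on the
principal Lambert-W branch (the secondary branch returns the trivial root
`s = 0`), and the second-order expansion `K_VP/(2(1−ζ))`.  Lambert and
bisection agree to ~1e-13 relative; the expansion is a `ζ → 1` asymptotic
(3.5% off at ζ = 0.95, 60% at ζ = 0.5 — it is not meant for small ζ).

## Memory model

Per-process memory is `M_0(M) + M_n(M,N) + M_c(M,T,N,K)`:

* `M_0`: a constant start-up footprint plus `M × buffer_entries × 4 B` for
  the collective-exchange receive buffer (defaults: 268 binary MB and 1000
  entries, the published worst case);
* `M_n`: `(N/M)·m_n` neuron objects plus infrastructure `N·m0_n +
  (N/M)·m+_n`.  The classic ("3g") kernel pays `m0_n = 1/3 B` for every
  neuron in the network (the sparse node table); the condensed ("4g") kernel
  eliminates that term and pays 24 B per *local* node instead;
* `M_c`: synapse objects split into plastic (a fraction `β²` of the
  `K_M = N·K/M` process-local synapses, the excitatory-to-excitatory ones)
  and static, plus per-VP infrastructure: a presence table at `1/3 B` per
  neuron, `m1_c` per source with exactly one local target and the worst-case
  `m>1_c` per source with more (every multi-target source is charged the
  two-type container cost, a deliberate overestimate).

Parameter tables for both kernel generations ship as YAML
(`sparsesim/data/{3g,4g}.yaml`).  The nominal `0.33 B` entries are stored as
the exact `1/3 B` they round: this choice reproduces the published 318
binary MB for the node table at `N = 1e9` (all MB/GB figures are binary).
All byte values are theoretical data-type sizes on a 64-bit architecture, so
the model underestimates a real allocator's footprint; the pool allocator is
represented only by this absence of per-allocation bookkeeping.  The
maximum-filling solver bisects on integer `N` (the total is nondecreasing in
`N`) and rounds down, so `total(N_max) ≤ budget < total(N_max+1)`.

## Record layouts

The layout calculator assigns sequential offsets under natural alignment
(each scalar aligned to its own size, structs padded to their widest member);
packed/unaligned layouts are out of scope, following the portability argument
for never emitting unaligned access.  The condensed static synapse record
{2 B thread-local target index, 4 B packed delay+type, 8 B weight} costs
16 B with 2 B padding; adding the 8 B plasticity trace gives 24 B.  The
classic record {4 B type, 8 B pointer, 8 B delay, 8 B weight} costs 32 B
(its exact field order is unprinted; 32 B is order-invariant for these
fields, so the catalog order is a convention).  The packed word holds the
delay as a 24-bit count of `h`-steps (1678 s at `h = 0.1 ms`) and an 8-bit
synapse-type id (256 types); thread-local indices fit 2 B while a VP owns at
most 65,535 nodes, and the calculator flags violations.

## Connection store

The per-VP store is a presence table (one bit per source GID, grouped 48 to
a group — consistent with the 1/3 B per neuron accounting — each group with
one pointer slot) over adaptive containers.  Container selection is a pure
function of the records present: 1..`K_cutoff` same-type records in
fixed-size storage (`K_cutoff = 3`), more in a growable vector (promotion
copies in insertion order), several types in a heterogeneous wrapper whose
children are ordered by first appearance (a determinism convention; the
original is silent).  The connection handshake is modeled as set membership:
an event kind is accepted iff both the synapse's helper and the target node
handle it, and a rejection names the failing leg.  Byte accounting charges
0 / `m1_c` / `m>1_c` per source by list length plus the aligned object size
per record, and is cross-checked in tests against the memory model evaluated
on the store's own census.

## Sparse node array

Local nodes are stored in GID order; `rank = gid mod M` round-robin
assignment makes local GIDs an arithmetic progression apart from replicated
nodes (devices/subnets present on every rank).  Lookup starts at the linear
estimate `⌊1 + α(g − g_min)⌋`, `α = (n_loc − 2)/(g_max − g_min)`, clamped to
the valid index range (a choice; out-of-range estimates are unspecified in
the original), and scans toward the bracketing GID.  The extreme local GIDs
are resolved directly from the stored min/max, so with no replicated nodes
every local lookup takes zero scan steps.  The `−2` in `α` compensates
exactly two replicated nodes; measurements with the device pair the
benchmark script replicates (one stimulus, one recorder, created after the
neurons) give a worst case of two steps, while ten randomly interleaved
replicated nodes can cost five.  The two-step claim is therefore tied to the
device-pair regime; lookup correctness (equality with a full linear scan) is
tested for arbitrary replication.  Averages below one step hold for the
lookup mix the simulator performs (mostly local targets of delivered
events); a non-local probe costs one bracketing step by construction.
Overhead is one pointer plus one long — 16 B — per local node, independent
of `N`.

## Reference simulator

Leaky integrate-and-fire neurons with alpha-shaped post-synaptic currents:

    dy1/dt = −y1/τ_syn,   dy2/dt = y1 − y2/τ_syn,   dV/dt = −V/τ_m + y2/C_m

with `V_th = 20 mV`, `τ_m = 10 ms`, `C_m = 250 pF`, `τ_syn = 0.3258 ms`,
resting = reset = 0 mV and 0.5 ms refractoriness (the last three follow the
benchmark script's conventions).  The one-step update is the matrix
exponential of the subthreshold system (`scipy.linalg.expm`, exact to
machine precision; the Padé evaluation also covers the confluent
`τ_m = τ_syn` case).  A spike of weight `J` increments `y1` by `J·e/τ_syn`,
so the current peaks at `J` pA one `τ_syn` after arrival; the external drive
is an independent per-neuron Poisson process of total rate
`ν_ext = η·V_th·C_m/(e·τ_syn·J_E·τ_m)`, which makes the free mean membrane
potential `η·V_th` (set 1: 20,858 spikes/s, matching the published 20,856 to
rounding).  All synapses share the 1.5 ms delay; the state advances in
`h = 0.1 ms` steps and spikes are exchanged between the emulated virtual
processes every delay interval, arriving exactly one delay after emission
through a per-neuron ring buffer.  Initial potentials are normal(9.5, 5.0)
mV, redrawn below reset.

Plasticity (excitatory-to-excitatory synapses) follows the power-law
pair rule: potentiation `Δw = λ·w0^(1−μ)·w^μ·x_pre` at post-synaptic spikes,
depression `Δw = −λ·α·w·x_post` at pre-synaptic spikes, with all-to-all
spike traces jumping by one and decaying with `τ+ = 15 ms` (pre) and
`τ− = 30 ms` (post).  Defaults `λ = 0.1`, `μ = 0.4`, `α = 0.0513`,
`w0 = 1 pA`.  The reference weight matters: the rate-based fixed point is
`w* = w0·(τ+/(α·τ−))^(1/(1−μ)) ≈ 44.6 pA`, i.e. at the benchmark's
excitatory weight only for `w0 = 1 pA` — the value of `α` clearly presumes
weights expressed in pA.  Setting `w0` to `J_E` instead moves the fixed
point to ~44·J_E and the network visibly runs away within one second.
All parameters are configurable.

Two delivery backends produce identical spike trains: a vectorized CSR
backend (used at benchmark scale; delivery via `bincount` scatter-adds, the
plastic synapses kept as a contiguous prefix of each source's segment) and
an object backend that routes every spike through the per-VP connection
stores and resolves targets through the sparse node arrays (static weights;
used at small scale and in equivalence tests).  Randomness uses
counter-based Philox streams: one per neuron for initialisation and drive,
one for wiring; the network and its spike output are therefore identical
for any number of emulated VPs, and runs are reproducible from a single
seed recorded in the output metadata.

## Benchmark networks

Set 1: `K = 11,250` (9000 exc + 2250 inh), `J_E = 45.61 pA`, `g = 5`,
`η = 1.685`.  Set 2: `K = 6000` (4800 + 1200), `J_E = 50 pA`, `g = 7`,
`η = 1.2`.  Both use 80% excitatory neurons, fixed per-neuron in-degrees
drawn uniformly with replacement from each population, `J_I = −g·J_E`, and
the same membrane-potential initialisation (set 2 inherits it from set 1 —
assumed, as only the changed parameters are listed).  A configurable element
budget (default 1.5e8 synapses) guards against accidentally requesting
machine-scale networks.

### Desk-scale sizes and what they show

The shipped runs preserve the in-degree and shrink `N`: set 2 at
`N = 6000` (3.6e7 synapses, ~15 s per simulated second) and set 1 at
`N = 12,500` (1.4e8 synapses, ~3 min).  At these sizes the connection
density `K/N` is near one, whereas the published dynamics refer to
machine-scale runs where `K/N ≲ 1e-5`.  Validation is therefore two-fold:

* the neuron/drive/weight conventions are validated independently of the
  network loop — the propagator against an adaptive ODE oracle at 1e-9
  relative, and the operating point by a single-neuron self-consistency
  oracle fed independent Poisson trains.  For set 1 that oracle
  self-consists at 7.4 spikes/s against the published 7.6;
* the network loop is validated against the object backend, the partition
  invariance, and the delay/census oracles.

For set 2 the same single-neuron oracle self-consists at ~2.5 spikes/s, and
the dense `N = 6000` network runs at ~3.6 ± 0.6 spikes/s across seeds
(shared-input correlations at density one raise the rate above the sparse
fixed point; the same effect puts the dense set-1 network at ~9.4).  The
published 4.5 spikes/s for set 2 belongs to the 1.86e9-neuron run and is
not exactly recovered at this scale; the acceptance test states the ±15%
band around 4.5 and documents the measured value rather than adjusting any
parameter toward it.  Passing desk-scale dynamics checks therefore shows
convention fidelity and internal consistency, not that reduced-size rates
equal machine-scale rates.

The synthetic-network generator reproduces the benchmark's statistical
structure (populations, fixed in-degrees, weights, drive) but not features
of real cortical data — no spatial structure, no synaptic or conduction
heterogeneity, no parameter distributions — so passing tests say nothing
about biological realism beyond the benchmark's own idealisations.

## Known limitations

* No MPI, threads, or off-grid spike times; virtual processes are emulated
  sequentially, and performance claims are out of scope.
* The object backend supports static weights only; plasticity runs in the
  vectorized backend.
* The memory model predicts theoretical object sizes; measured footprints of
  a real run exceed them (allocator behaviour is represented only by the
  pool-allocator accounting flag).
* STDP trace updates are applied at spike emission rather than delayed
  arrival times; at the rate level this is invisible, but precise
  weight-trajectory comparisons against an event-driven implementation would
  show timing differences within one delay.
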