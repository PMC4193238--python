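"""Benchmark network builders, dry-run planning, and theory verification.

Two parameter sets define the balanced random network used throughout the
package.  Both use 80% excitatory / 20% inhibitory integrate-and-fire
neurons, fixed per-neuron in-degrees split proportionally between the
populations, inhibition ``J_I = -g * J_E``, and an external Poisson drive
calibrated by the suprathreshold factor ``eta`` (free mean membrane potential
``eta * V_th``):

* set 1: K = 11,250 (9000 exc + 2250 inh), J_E = 45.61 pA, g = 5, eta = 1.685;
* set 2: K = 6000 (4800 exc + 1200 inh), J_E = 50 pA, g = 7, eta = 1.2 —
  tuned for an irregular state at about 4.5 spikes/s.

Excitatory-to-excitatory synapses are plastic (STDP); all others static.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .combinatorics import MachineGrid, NetworkShape, expected_list_counts
from .memory_model import (
    MachineBudget,
    MemoryBreakdown,
    MemoryParams,
    max_network_size,
    total_memory,
)
from .simulator import Network, NeuronParams, StdpParams, external_rate

__all__ = [
    "BenchmarkSet",
    "SET1",
    "SET2",
    "benchmark_set",
    "build_network",
    "dry_run",
    "DryRunReport",
    "verify_combinatorics",
]

#: Desk-scale safety guard: refuse to wire more synapses than this.
DEFAULT_ELEMENT_BUDGET = 150_000_000


@dataclass(frozen=True)
class BenchmarkSet:
    """Parameters of one benchmark network configuration."""

    set_id: int
    K: int  # total in-degree per neuron
    K_exc: int
    K_inh: int
    J_E: float  # excitatory weight, pA (PSC peak amplitude)
    g: float  # relative inhibitory strength; J_I = -g * J_E
    eta: float  # external drive in units of the threshold-crossing rate
    beta: float = 0.8  # excitatory fraction
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if self.K_exc + self.K_inh != self.K:
            raise ValueError("exc and inh in-degrees must sum to K")

    @property
    def J_I(self) -> float:
        return -self.g * self.J_E

    @property
    def nu_ext(self) -> float:
        """External Poisson rate per neuron, spikes/s."""
        return external_rate(self.eta, self.neuron, self.J_E)


SET1 = BenchmarkSet(set_id=1, K=11250, K_exc=9000, K_inh=2250, J_E=45.61, g=5.0, eta=1.685)
SET2 = BenchmarkSet(set_id=2, K=6000, K_exc=4800, K_inh=1200, J_E=50.0, g=7.0, eta=1.2)


def benchmark_set(set_id: int) -> BenchmarkSet:
    if set_id == 1:
        return SET1
    if set_id == 2:
        return SET2
    raise ValueError(f"unknown benchmark set {set_id}; choose 1 or 2")


def build_network(
    bench: BenchmarkSet,
    N: int,
    n_vp: int = 1,
    seed: int = 0,
    element_budget: int = DEFAULT_ELEMENT_BUDGET,
    stdp: StdpParams | None = None,
) -> Network:
    """Wire a benchmark network of ``N`` neurons with fixed in-degrees.

    Each neuron draws exactly ``K_exc`` sources uniformly (with replacement)
    from the ``0.8 N`` excitatory neurons and ``K_inh`` from the inhibitory
    ones.  Wiring uses one counter-based substream per target neuron, so the
    result depends only on ``(bench, N, seed)`` — not on ``n_vp``.

    Raises
    ------
    ValueError
        If ``N * K`` exceeds ``element_budget`` (guard against accidental
        supercomputer-sized requests on a desk machine).
    """
    if n_vp < 1:
        raise ValueError("n_vp must be >= 1")
    if N * bench.K > element_budget:
        raise ValueError(
            f"requested {N * bench.K:.2e} synapses exceeds the element budget "
            f"{element_budget:.2e}; lower N or raise element_budget explicitly"
        )
    n_exc = int(round(bench.beta * N))
    n_inh = N - n_exc
    if bench.K_inh > 0 and n_inh == 0:
        raise ValueError("network too small: no inhibitory neurons")
    K = bench.K
    g = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    )
    # target-major draw: row j holds the K_exc + K_inh sources of neuron j
    sources = np.empty((N, K), dtype=np.int32)
    sources[:, : bench.K_exc] = g.integers(0, n_exc, (N, bench.K_exc), dtype=np.int32)
    sources[:, bench.K_exc :] = g.integers(n_exc, N, (N, bench.K_inh), dtype=np.int32)
    sources = sources.ravel()
    targets = np.repeat(np.arange(N, dtype=np.int32), K)
    # re-order into source-major CSR, plastic (exc-target) synapses first in
    # each segment so they form a contiguous prefix; stable sort keeps the
    # creation order within each (source, plasticity) class
    key = sources.astype(np.int64) * 2 + (targets >= n_exc)
    order = np.argsort(key, kind="stable")
    del key
    sources = sources[order]
    targets = targets[order]
    del order
    indptr = np.concatenate(
        ([0], np.cumsum(np.bincount(sources, minlength=N)))
    ).astype(np.int64)
    exc_target_counts = np.bincount(
        sources[targets < n_exc], minlength=N
    ).astype(np.int64)
    stdp_end = indptr[:-1] + exc_target_counts
    stdp_end[n_exc:] = indptr[:-1][n_exc:]  # inhibitory sources are never plastic
    weights = np.where(sources < n_exc, bench.J_E, bench.J_I).astype(np.float64)
    stdp_params = stdp if stdp is not None else StdpParams()
    return Network(
        N=N,
        n_exc=n_exc,
        indptr=indptr,
        syn_source=sources,
        syn_target=targets,
        syn_weight=weights,
        syn_stdp_end=stdp_end,
        J_E=bench.J_E,
        nu_ext=bench.nu_ext,
        n_vp=n_vp,
        seed=seed,
        neuron=bench.neuron,
        stdp=stdp_params,
    )


@dataclass
class DryRunReport:
    """Memory prediction for the largest network fitting a machine."""

    N_max: int
    breakdown: MemoryBreakdown
    list_counts: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "N_max": self.N_max,
            "breakdown": self.breakdown.as_dict(),
            "list_counts": self.list_counts,
        }


def dry_run(
    grid: MachineGrid,
    bench: BenchmarkSet,
    budget: MachineBudget,
    generation: str = "4g",
) -> DryRunReport:
    """Single-process planning pass: predicted maximum network size and its
    memory breakdown plus the expected target-list census per VP."""
    params = replace(MemoryParams.from_generation(generation), beta=bench.beta)
    n_max = max_network_size(grid, bench.K, params, budget)
    if n_max >= 2:
        shape = NetworkShape(n_max, bench.K)
        breakdown = total_memory(grid, shape, params, budget)
        stats = expected_list_counts(grid, shape, mode="exact")
        counts = stats.as_dict()
    else:
        breakdown = MemoryBreakdown()
        breakdown.base, breakdown.buffer = (
            budget.base_bytes,
            grid.M * budget.buffer_entries * budget.buffer_entry_bytes,
        )
        counts = {}
    return DryRunReport(n_max, breakdown, counts)


def _stratified_theory(bench: BenchmarkSet, N: int, n_vp: int) -> dict[str, float]:
    """Exact expected list-length census for the stratified (exc/inh) wiring.

    A source of population X (size N_X, per-target in-degree K_X) appears in
    each of the ``N_VP * K_X`` VP-local draws from X with probability
    ``1/N_X``; the population-averaged census reduces to the uniform-wiring
    closed forms when in-degrees are proportional to population sizes.
    """
    n_exc = int(round(bench.beta * N))
    n_vp_local = N / n_vp
    out = {"n_empty": 0.0, "n_one": 0.0, "n_multi": 0.0}
    for n_x, k_x in ((n_exc, bench.K_exc), (N - n_exc, bench.K_inh)):
        if n_x == 0:
            continue
        draws = n_vp_local * k_x
        q = 1.0 - 1.0 / n_x
        p_empty = q**draws
        p_one = q ** (draws - 1.0) * draws / n_x
        out["n_empty"] += p_empty * n_x
        out["n_one"] += p_one * n_x
        out["n_multi"] += (1.0 - p_empty - p_one) * n_x
    return out


def verify_combinatorics(network: Network, bench: BenchmarkSet) -> dict:
    """Empirical per-VP target-list census against the closed-form theory.

    Counts, for every (source, VP) pair, how many VP-local targets the
    source has, and compares the numbers of empty/singleton/longer lists
    (averaged over VPs) with the expected counts, reporting z-scores under
    the binomial standard error.
    """
    N, n_vp = network.N, network.n_vp
    vp_of_target = (network.syn_target.astype(np.int64) + 1) % n_vp
    # per (source, vp) local-target counts via a flattened bincount
    pair = network.syn_source.astype(np.int64) * n_vp + vp_of_target
    lengths = np.bincount(pair, minlength=N * n_vp)
    n_one = int(np.count_nonzero(lengths == 1))
    n_multi = int(np.count_nonzero(lengths > 1))
    n_empty = N * n_vp - n_one - n_multi
    empirical = {
        "n_empty": n_empty / n_vp,
        "n_one": n_one / n_vp,
        "n_multi": n_multi / n_vp,
    }
    theory = _stratified_theory(bench, N, n_vp)
    report = {"empirical": empirical, "theory": theory, "z": {}, "n_vp": n_vp}
    for key in ("n_empty", "n_one", "n_multi"):
        p = theory[key] / N
        se = np.sqrt(max(N * p * (1.0 - p), 1e-300) * n_vp) / n_vp
        report["z"][key] = (empirical[key] - theory[key]) / se if se > 0 else 0.0
    return report
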