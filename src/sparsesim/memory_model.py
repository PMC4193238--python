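"""Per-process memory model of a distributed spiking-network simulator.

The memory consumption of one MPI process is

    M_total(M, T, N, K) = M_0(M) + M_n(M, N) + M_c(M, T, N, K)

where ``M_0`` is the start-up footprint plus the MPI receive buffer (which
grows linearly with the number of processes ``M``), ``M_n`` the neurons, and
``M_c`` the synapses and their per-VP infrastructure.  The connection term is
driven by the target-list combinatorics: each of the ``T`` VPs of a process
pays a presence-table bit per neuron in the whole network, a small fixed
overhead for each source with exactly one local target, and a larger one for
each source with several.

Parameter tables for the 3rd- and 4th-generation kernels ship as editable
YAML files (``sparsesim/data/{3g,4g}.yaml``); all byte costs are theoretical
data-type sizes on a 64-bit architecture, so the model slightly underestimates
a real allocator's footprint.  Megabyte/gigabyte conventions in reports are
binary (2**20, 2**30 B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .combinatorics import MachineGrid, NetworkShape, expected_list_counts

__all__ = [
    "MemoryParams",
    "MachineBudget",
    "MemoryBreakdown",
    "base_memory",
    "neuron_memory",
    "connection_memory",
    "total_memory",
    "max_network_size",
    "K_BUDGET_BYTES",
]

#: Usable memory per process on a 16 GB node of the K computer (13.81 binary GB).
K_BUDGET_BYTES = int(13.81 * 2**30)


@dataclass(frozen=True)
class MemoryParams:
    """Byte costs of one kernel generation (see ``data/*.yaml`` for values)."""

    generation: str
    m_n: float  # one neuron object
    m0_n: float  # per-neuron node infrastructure (scales with total N)
    mplus_n: float  # per local neuron
    mempty_n: float  # per non-local neuron
    m_stat_c: float  # one static synapse object
    m_stdp_c: float  # one STDP synapse object
    m0_c: float  # per-neuron presence-table cost (per VP)
    m1_c: float  # per source with exactly one local target
    mgt1_c: float  # per source with more than one local target
    mempty_c: float  # per source without local targets
    beta: float = 0.8  # excitatory fraction

    def __post_init__(self) -> None:
        for name in (
            "m_n", "m0_n", "mplus_n", "mempty_n", "m_stat_c",
            "m_stdp_c", "m0_c", "m1_c", "mgt1_c", "mempty_c",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    @classmethod
    def from_generation(cls, generation: str) -> "MemoryParams":
        """Load the shipped parameter table for ``"3g"`` or ``"4g"``."""
        ref = resources.files("sparsesim").joinpath("data", f"{generation}.yaml")
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise ValueError(f"unknown kernel generation {generation!r}") from None
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MemoryParams":
        return cls(**mapping)


@dataclass(frozen=True)
class MachineBudget:
    """Per-process memory budget and communication-buffer geometry.

    The receive buffer holds ``buffer_entries`` 4 B entries from each of the
    ``M`` processes (collective spike exchange), hence grows linearly in
    ``M``.  ``budget_bytes`` is the memory actually usable by the program
    (e.g. 13.81 of the nominal 16 GB per node on the K computer).
    """

    base_bytes: float = 268 * 2**20
    buffer_entry_bytes: int = 4
    buffer_entries: int = 1000
    budget_bytes: float = K_BUDGET_BYTES


@dataclass
class MemoryBreakdown:
    """Per-process memory by component, in bytes."""

    base: float = 0.0
    buffer: float = 0.0
    neuron_objects: float = 0.0
    neuron_infra: float = 0.0
    sparse_table: float = 0.0
    infra_singleton: float = 0.0
    infra_multi: float = 0.0
    synapses_static: float = 0.0
    synapses_stdp: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.base
            + self.buffer
            + self.neuron_objects
            + self.neuron_infra
            + self.sparse_table
            + self.infra_singleton
            + self.infra_multi
            + self.synapses_static
            + self.synapses_stdp
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "base": self.base,
            "buffer": self.buffer,
            "neuron_objects": self.neuron_objects,
            "neuron_infra": self.neuron_infra,
            "sparse_table": self.sparse_table,
            "infra_singleton": self.infra_singleton,
            "infra_multi": self.infra_multi,
            "synapses_static": self.synapses_static,
            "synapses_stdp": self.synapses_stdp,
        }
        d["total"] = self.total
        return d


def base_memory(M: int, budget: MachineBudget) -> tuple[float, float]:
    """Start-up footprint and receive-buffer bytes for ``M`` processes."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return budget.base_bytes, M * budget.buffer_entries * budget.buffer_entry_bytes


def neuron_memory(N: float, M: int, params: MemoryParams) -> tuple[float, float]:
    """Per-process neuron memory: ``(objects_bytes, infra_bytes)``.

    The infrastructure term ``N * m0_n`` (3g sparse table of nodes) scales
    with the *total* network size; the 4g sparse node array removes it
    (``m0_n = 0``), leaving only the per-local-node pointer + GID cost.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    n_local = N / M
    objects = n_local * params.m_n
    infra = N * params.m0_n + n_local * params.mplus_n
    return objects, infra


def _list_counts(grid: MachineGrid, shape: NetworkShape):
    # exact closed forms need N >= 2; below that everything is degenerate
    if shape.N >= 2:
        return expected_list_counts(grid, shape, mode="exact")
    stats = expected_list_counts(grid, NetworkShape(2, shape.K), mode="exact")
    scale = shape.N / 2.0
    stats.n_empty *= scale
    stats.n_one *= scale
    stats.n_multi *= scale
    return stats


def connection_memory(
    grid: MachineGrid, shape: NetworkShape, params: MemoryParams
) -> MemoryBreakdown:
    """Per-process connection memory: synapse objects plus infrastructure.

    Synapse objects split into STDP (a fraction ``beta**2`` of the
    ``K_M = N*K/M`` local synapses: the excitatory-to-excitatory ones) and
    static.  Infrastructure is per VP, hence the factor ``T``: a presence
    table over all ``N`` neurons plus per-source container overheads keyed
    to the expected list-length census.  Every source with two or more
    local targets is charged the same worst-case overhead ``mgt1_c``.
    """
    br = MemoryBreakdown()
    if shape.K == 0:
        return br
    k_m = shape.N * shape.K / grid.M
    k_stdp = k_m * params.beta**2
    br.synapses_stdp = k_stdp * params.m_stdp_c
    br.synapses_static = (k_m - k_stdp) * params.m_stat_c
    br.sparse_table = grid.T * shape.N * params.m0_c
    stats = _list_counts(grid, shape)
    br.infra_singleton = grid.T * stats.n_one * params.m1_c
    br.infra_multi = grid.T * (shape.N - stats.n_empty - stats.n_one) * params.mgt1_c
    return br


def total_memory(
    grid: MachineGrid,
    shape: NetworkShape,
    params: MemoryParams,
    budget: MachineBudget,
) -> MemoryBreakdown:
    """Full per-process breakdown ``M_0 + M_n + M_c``."""
    br = connection_memory(grid, shape, params)
    br.base, br.buffer = base_memory(grid.M, budget)
    br.neuron_objects, br.neuron_infra = neuron_memory(shape.N, grid.M, params)
    return br


def max_network_size(
    grid: MachineGrid,
    K: float,
    params: MemoryParams,
    budget: MachineBudget,
) -> int:
    """Largest integer ``N`` whose predicted footprint fits ``budget_bytes``.

    Bisection on ``N`` (the total is nondecreasing in ``N``); ties broken
    downward, so ``total(N_max) <= budget < total(N_max + 1)``.

    Raises
    ------
    ValueError
        If even the empty network (base + buffer) exceeds the budget.
    """
    def fits(n: int) -> bool:
        shape = NetworkShape(n, K) if n >= 1 else None
        if shape is None:
            base, buf = base_memory(grid.M, budget)
            return base + buf <= budget.budget_bytes
        return total_memory(grid, shape, params, budget).total <= budget.budget_bytes

    if not fits(0):
        raise ValueError("infeasible: base memory alone exceeds the budget")
    lo, hi = 0, 1024
    while fits(hi):
        lo, hi = hi, hi * 16
        if hi > 10**15:  # no realistic budget reaches this
            return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fits(mid):
            lo = mid
        else:
            hi = mid
    return lo
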