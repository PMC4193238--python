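"""Target-list combinatorics for randomly wired networks on parallel machines.

When a network of ``N`` neurons with mean in-degree ``K`` is distributed over
``M * T`` virtual processes (VPs), each VP holds ``K_VP = N*K/(M*T)`` synapses.
Under uniform random wiring with replacement, the number of VP-local targets of
a given source neuron is binomially distributed, and on large machines
(``K/(M*T) << 1``) almost every source has zero or one local target.  This
module provides the closed-form probabilities of empty / singleton / longer
target lists, the expected list counts per VP, and the network size ``N_zeta``
at which the number of non-empty lists reaches a fraction ``zeta`` of its
weak-scaling maximum ``K_VP``.

The connectivity law throughout the package: each of the ``K_VP`` local
synapses draws its source independently and uniformly from all ``N`` neurons,
with replacement (multapses and autapses allowed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "MachineGrid",
    "NetworkShape",
    "TargetListStats",
    "target_list_probabilities",
    "conditional_singleton_probability",
    "expected_list_counts",
    "network_size_at_fill_fraction",
]


@dataclass(frozen=True)
class MachineGrid:
    """Machine geometry: ``M`` MPI processes running ``T`` threads each.

    Threads are the units of data-structure replication ("virtual
    processes"); only the product ``M*T`` enters the combinatorics.
    """

    M: int
    T: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1:
            raise ValueError(f"M and T must be >= 1, got M={self.M}, T={self.T}")

    @property
    def n_vp(self) -> int:
        """Total number of virtual processes ``M*T``."""
        return self.M * self.T


@dataclass(frozen=True)
class NetworkShape:
    """Network size ``N`` and mean in-degree ``K`` (``K`` may be non-integer)."""

    N: float
    K: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")

    def n_vp_local(self, grid: MachineGrid) -> float:
        """Average number of VP-local neurons ``N_VP = N/(M*T)``."""
        return self.N / grid.n_vp

    def k_vp_local(self, grid: MachineGrid) -> float:
        """Average number of VP-local synapses ``K_VP = N_VP * K``."""
        return self.n_vp_local(grid) * self.K


@dataclass
class TargetListStats:
    """Probabilities and expected per-VP counts of target-list lengths 0/1/>1."""

    p_empty: float
    p_one: float
    p_multi: float
    n_empty: float = field(default=0.0)
    n_one: float = field(default=0.0)
    n_multi: float = field(default=0.0)

    @property
    def n_nonempty(self) -> float:
        return self.n_one + self.n_multi

    def as_dict(self) -> dict[str, float]:
        return {
            "p_empty": self.p_empty,
            "p_one": self.p_one,
            "p_multi": self.p_multi,
            "n_empty": self.n_empty,
            "n_one": self.n_one,
            "n_multi": self.n_multi,
            "n_nonempty": self.n_nonempty,
        }


def target_list_probabilities(
    grid: MachineGrid, shape: NetworkShape, mode: str = "exact"
) -> TargetListStats:
    """Probabilities that a source neuron has 0, 1, or >1 VP-local targets.

    Parameters
    ----------
    grid, shape
        Machine geometry and network size.
    mode
        ``"exact"`` evaluates the finite-N binomial forms

        .. math::
            p_\\emptyset = (1 - 1/N)^{K_{VP}}, \\qquad
            p_1 = (1 - 1/N)^{K_{VP}-1} \\, K_{VP}/N,

        ``"poisson_limit"`` the large-N Poisson limit
        ``exp(-K/MT)`` and ``exp(-K/MT) * K/MT``.  In both modes
        ``p_multi`` is the remainder, so the three sum to one exactly.
    """
    if mode not in ("exact", "poisson_limit"):
        raise ValueError(f"unknown mode {mode!r}")
    if shape.K == 0:
        return TargetListStats(1.0, 0.0, 0.0)
    if mode == "poisson_limit":
        lam = shape.K / grid.n_vp
        p_empty = math.exp(-lam)
        p_one = p_empty * lam
    else:
        if shape.N < 2:
            raise ValueError("exact mode requires N >= 2")
        k_vp = shape.k_vp_local(grid)
        q = 1.0 - 1.0 / shape.N
        p_empty = q**k_vp
        # the binomial form presumes at least one draw; for fractional
        # K_VP < 1 the singleton probability is capped by the remainder
        p_one = min(q ** (k_vp - 1.0) * k_vp / shape.N, 1.0 - p_empty)
    p_multi = max(1.0 - p_empty - p_one, 0.0)
    return TargetListStats(p_empty, p_one, p_multi)


def conditional_singleton_probability(
    grid: MachineGrid, shape: NetworkShape, mode: str = "exact"
) -> tuple[float, float]:
    """P(exactly one local target | at least one) and its complement.

    On petascale machines the first value approaches ``1 - K/(2MT)``: a
    non-empty target list almost surely holds a single synapse.

    Raises
    ------
    ValueError
        In the empty-only regime ``K = 0`` where the condition has
        probability zero.
    """
    stats = target_list_probabilities(grid, shape, mode)
    denom = stats.p_one + stats.p_multi
    if denom <= 0.0:
        raise ValueError("conditional probability undefined: no non-empty lists (K=0)")
    p1 = stats.p_one / denom
    return p1, 1.0 - p1


def expected_list_counts(
    grid: MachineGrid, shape: NetworkShape, mode: str = "exact"
) -> TargetListStats:
    """Expected numbers of empty / singleton / longer target lists per VP.

    Counts are ``probability * N``; the number of non-empty lists
    ``(1 - p_empty) * N`` approaches ``K_VP`` under weak scaling
    (fixed ``N_VP`` and ``K``, growing machine).
    """
    stats = target_list_probabilities(grid, shape, mode)
    stats.n_empty = stats.p_empty * shape.N
    stats.n_one = stats.p_one * shape.N
    stats.n_multi = stats.p_multi * shape.N
    return stats


def _fill_fraction_residual(n: float, k_vp: float, zeta: float) -> float:
    return (1.0 - math.exp(-k_vp / n)) * n - zeta * k_vp


def network_size_at_fill_fraction(
    k_vp: float, zeta: float, method: str = "bisect"
) -> float:
    """Network size ``N_zeta`` at which a fraction ``zeta`` of the maximal
    number of target lists ``K_VP`` is non-empty.

    Solves ``zeta * K_VP = (1 - exp(-K_VP/N)) * N`` for ``N``.

    Parameters
    ----------
    k_vp
        Number of VP-local synapses (> 0).
    zeta
        Fill fraction, strictly between 0 and 1.
    method
        ``"bisect"`` — root bracketing (reference method);
        ``"lambert"`` — closed form via the principal branch of the
        Lambert-W function, ``N = -K_VP / s`` with
        ``s = -1/zeta - W0(-exp(-1/zeta)/zeta)``;
        ``"approx"`` — second-order expansion ``K_VP / (2(1-zeta))``,
        accurate as ``zeta -> 1``.
    """
    if not 0.0 < zeta < 1.0:
        raise ValueError(f"zeta must lie strictly in (0, 1), got {zeta}")
    if k_vp <= 0:
        raise ValueError(f"k_vp must be > 0, got {k_vp}")
    if method == "approx":
        return k_vp / (2.0 * (1.0 - zeta))
    if method == "lambert":
        # W-1 branch gives the trivial root s=0 (N -> inf); W0 the finite one.
        y = lambertw(-math.exp(-1.0 / zeta) / zeta, k=0).real
        s = -1.0 / zeta - y
        return -k_vp / s
    if method == "bisect":
        lo = zeta * k_vp * 1e-6
        hi = 10.0 * k_vp / (1.0 - zeta)
        while _fill_fraction_residual(hi, k_vp, zeta) <= 0.0:
            hi *= 10.0
        return brentq(
            lambda n: _fill_fraction_residual(n, k_vp, zeta),
            lo,
            hi,
            xtol=1e-12,
            rtol=8.9e-16,
        )
    raise ValueError(f"unknown method {method!r}")
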