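"""Local-node storage with linear-estimate GID lookup.

Neurons are assigned to MPI ranks round-robin (``rank = gid mod M``), so the
GIDs local to one rank are — apart from a small number of *replicated* nodes
(devices and subnets present on every rank) — an arithmetic progression.  The
sparse node array stores local nodes in creation (GID) order and looks a GID
up by linear interpolation between the smallest and largest local GID,
followed by a short scan.  The structure costs one pointer plus one long
(16 B) per *local* node, independent of the total network size, which is what
removes the N-proportional node-infrastructure term of earlier kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterator, Sequence

__all__ = ["LocalNodeEntry", "LookupResult", "SparseNodeArray", "rank_of"]

#: Bytes of overhead per local node: one pointer and one long (the GID).
OVERHEAD_PER_NODE = 16


def rank_of(gid: int, M: int) -> int:
    """MPI rank owning ``gid`` under round-robin assignment: ``gid mod M``."""
    if gid < 0 or M < 1:
        raise ValueError("gid >= 0 and M >= 1 required")
    return gid % M


@dataclass(frozen=True)
class LocalNodeEntry:
    gid: int
    node: Any


@dataclass(frozen=True)
class LookupResult:
    node: Any  # None when the GID is not local
    steps: int  # scan moves away from the initial estimate

    @property
    def is_local(self) -> bool:
        return self.node is not None


class SparseNodeArray:
    """Ordered array of local nodes with interpolation-based GID lookup.

    Parameters
    ----------
    local_nodes
        ``(gid, node)`` pairs in strictly increasing GID order (creation
        order).  GID 0 (the root network, local everywhere) must not be
        included.
    max_gid
        Largest GID in the whole network; lookups beyond it are invalid.
    """

    def __init__(self, local_nodes: Sequence[tuple[int, Any]], max_gid: int):
        gids = [g for g, _ in local_nodes]
        if any(b <= a for a, b in zip(gids, gids[1:])):
            raise ValueError("local GIDs must be strictly increasing")
        if gids and gids[-1] > max_gid:
            raise ValueError("local GID exceeds max_gid")
        self.entries = [LocalNodeEntry(g, n) for g, n in local_nodes]
        self.max_gid = max_gid
        self.n_loc = len(self.entries)
        self.g_loc_min = gids[0] if gids else 0
        self.g_loc_max = gids[-1] if gids else 0
        if self.n_loc >= 2 and self.g_loc_max > self.g_loc_min:
            self.alpha = (self.n_loc - 2) / (self.g_loc_max - self.g_loc_min)
        else:
            self.alpha = 0.0  # degenerate: direct scan
        # lookup instrumentation
        self.n_lookups = 0
        self.total_steps = 0
        self.max_steps = 0

    @property
    def overhead_bytes(self) -> int:
        """16 B per local node; independent of the total network size."""
        return self.n_loc * OVERHEAD_PER_NODE

    def _estimate_index(self, gid: int) -> int:
        est = int(1 + self.alpha * (gid - self.g_loc_min))
        return min(max(est, 0), self.n_loc - 1)

    def lookup(self, gid: int) -> LookupResult:
        """Locate ``gid``: ``(node, steps)``, node ``None`` when not local.

        Starts at the interpolated index and scans toward smaller or larger
        GIDs until the GID is found or bracketed.  ``steps`` counts the scan
        moves; with round-robin assignment and no replicated nodes the
        estimate is exact and ``steps`` is 0 (the extreme local GIDs are
        resolved directly from the stored min/max).
        """
        if gid < 0 or gid > self.max_gid:
            raise ValueError(f"invalid GID {gid}: network holds GIDs 0..{self.max_gid}")
        result = self._search(gid)
        self.n_lookups += 1
        self.total_steps += result.steps
        self.max_steps = max(self.max_steps, result.steps)
        return result

    def _search(self, gid: int) -> LookupResult:
        if self.n_loc == 0 or gid < self.g_loc_min or gid > self.g_loc_max:
            return LookupResult(None, 0)
        if gid == self.g_loc_min:
            return LookupResult(self.entries[0].node, 0)
        if gid == self.g_loc_max:
            return LookupResult(self.entries[-1].node, 0)
        idx = self._estimate_index(gid)
        steps = 0
        if self.entries[idx].gid <= gid:
            while self.entries[idx].gid < gid:
                idx += 1
                steps += 1
        else:
            while self.entries[idx].gid > gid:
                idx -= 1
                steps += 1
        entry = self.entries[idx]
        return LookupResult(entry.node if entry.gid == gid else None, steps)

    def __iter__(self) -> Iterator[LocalNodeEntry]:
        """Direct iteration over local nodes in ascending GID order."""
        return iter(self.entries)

    def __len__(self) -> int:
        return self.n_loc

    def instrumentation(self) -> dict[str, float]:
        """Lookup statistics accumulated since construction."""
        mean = self.total_steps / self.n_lookups if self.n_lookups else 0.0
        return {
            "n_lookups": self.n_lookups,
            "mean_steps": mean,
            "max_steps": self.max_steps,
        }
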