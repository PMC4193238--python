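"""Executable semantics of the adaptive per-VP connection infrastructure.

One :class:`ConnectionStore` holds the outgoing synapses of every source
neuron toward the targets local to a single virtual process.  A sparse
presence table — a bit per source GID, organised in fixed-size groups — marks
which sources have any local targets; only those own an inner container.
Containers adapt to their content:

* 1 .. ``K_cutoff`` records of one type: a fixed-size homogeneous container
  (storage grows by copy on each add, mirroring the recursive fixed-capacity
  template chain);
* more than ``K_cutoff`` records of one type: the container is promoted to a
  growable vector, copying records in insertion order;
* records of several types: a heterogeneous wrapper holding one homogeneous
  child per type, ordered by first appearance.

This module models the container semantics and the byte accounting; it does
not emulate allocator behaviour (the pool allocator only shows up in the
memory model as the absence of per-allocation bookkeeping bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from . import object_layout
from .memory_model import MemoryParams
from .object_layout import pack_delay_type, unpack_delay_type

__all__ = [
    "K_CUTOFF",
    "ConnectionRecord",
    "HomogeneousContainer",
    "HeterogeneousContainer",
    "SparsePresenceTable",
    "ConnectionStore",
    "HandshakeResult",
    "handshake",
]

#: Number of same-type records up to which fixed-size storage is used.
K_CUTOFF = 3

#: Source GIDs per presence-table group (48 bits ~ 16 B per group at 1/3 B each).
DEFAULT_GROUP_SIZE = 48


@dataclass(frozen=True)
class ConnectionRecord:
    """One synapse: 2 B target index, 4 B packed delay+type, doubles for state."""

    target_index: int
    packed: int
    weight: float
    trace: float | None = None  # STDP synapses carry the pre-synaptic trace

    @classmethod
    def create(
        cls,
        target_index: int,
        delay_steps: int,
        syn_id: int,
        weight: float,
        trace: float | None = None,
    ) -> "ConnectionRecord":
        if delay_steps < 1:
            raise ValueError("delay must be at least one step")
        return cls(target_index, pack_delay_type(delay_steps, syn_id), weight, trace)

    @property
    def delay_steps(self) -> int:
        return unpack_delay_type(self.packed)[0]

    @property
    def syn_id(self) -> int:
        return unpack_delay_type(self.packed)[1]


class StorageKind(Enum):
    FIXED = "fixed"
    GROWABLE = "growable"


class HomogeneousContainer:
    """Records of a single synapse type; fixed storage up to ``K_cutoff``."""

    def __init__(self, syn_id: int, k_cutoff: int = K_CUTOFF):
        self.syn_id = syn_id
        self.k_cutoff = k_cutoff
        self.kind = StorageKind.FIXED
        self._records: tuple[ConnectionRecord, ...] | list[ConnectionRecord] = ()

    def add(self, record: ConnectionRecord) -> None:
        if record.syn_id != self.syn_id:
            raise ValueError("record type differs from container type")
        if self.kind is StorageKind.FIXED:
            if len(self._records) + 1 > self.k_cutoff:
                # promotion: copy the fixed records into a growable vector
                self.kind = StorageKind.GROWABLE
                self._records = list(self._records)
                self._records.append(record)
            else:
                self._records = (*self._records, record)
        else:
            self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ConnectionRecord]:
        return iter(self._records)


class HeterogeneousContainer:
    """Wrapper holding one homogeneous child per synapse type in local use."""

    def __init__(self, children: Iterable[HomogeneousContainer]):
        self.children = list(children)
        if len(self.children) < 2:
            raise ValueError("heterogeneous container requires >= 2 children")
        ids = [c.syn_id for c in self.children]
        if len(set(ids)) != len(ids):
            raise ValueError("children must have pairwise distinct syn_ids")

    def add(self, record: ConnectionRecord, k_cutoff: int = K_CUTOFF) -> None:
        for child in self.children:
            if child.syn_id == record.syn_id:
                child.add(record)
                return
        child = HomogeneousContainer(record.syn_id, k_cutoff)
        child.add(record)
        self.children.append(child)

    def __len__(self) -> int:
        return sum(len(c) for c in self.children)

    def __iter__(self) -> Iterator[ConnectionRecord]:
        for child in self.children:
            yield from child


class SparsePresenceTable:
    """Bit per source GID, in equally sized groups with a pointer slot each."""

    def __init__(self, n_gids: int, group_size: int = DEFAULT_GROUP_SIZE):
        if n_gids < 0 or group_size < 1:
            raise ValueError("n_gids >= 0 and group_size >= 1 required")
        self.n_gids = n_gids
        self.group_size = group_size
        self.n_groups = -(-n_gids // group_size) if n_gids else 0
        self._bits = [0] * self.n_groups
        # pointer slot per group: maps gid -> inner container
        self._slots: list[dict[int, object]] = [dict() for _ in range(self.n_groups)]

    def _locate(self, gid: int) -> tuple[int, int]:
        if not 0 <= gid < self.n_gids:
            raise IndexError(f"gid {gid} outside table range [0, {self.n_gids})")
        return divmod(gid, self.group_size)

    def is_set(self, gid: int) -> bool:
        g, b = self._locate(gid)
        return bool(self._bits[g] >> b & 1)

    def get(self, gid: int):
        g, b = self._locate(gid)
        if not self._bits[g] >> b & 1:
            return None
        return self._slots[g][gid]

    def put(self, gid: int, inner: object) -> None:
        g, b = self._locate(gid)
        self._bits[g] |= 1 << b
        self._slots[g][gid] = inner

    def bit_count(self) -> int:
        return sum(bits.bit_count() for bits in self._bits)

    def __iter__(self) -> Iterator[int]:
        """Yield set GIDs in ascending order."""
        for g, bits in enumerate(self._bits):
            base = g * self.group_size
            while bits:
                low = bits & -bits
                yield base + low.bit_length() - 1
                bits ^= low


class ConnectionStore:
    """Per-VP connection infrastructure: presence table + adaptive containers."""

    def __init__(
        self,
        n_gids: int,
        n_local_nodes: int,
        k_cutoff: int = K_CUTOFF,
        group_size: int = DEFAULT_GROUP_SIZE,
    ):
        self.table = SparsePresenceTable(n_gids, group_size)
        self.n_local_nodes = n_local_nodes
        self.k_cutoff = k_cutoff

    def add_connection(self, source_gid: int, record: ConnectionRecord) -> None:
        """Insert ``record`` into the container of ``source_gid``.

        Container selection: no container yet -> fixed(1); a homogeneous
        container of the same type grows (promoting past ``K_cutoff``); a
        differing type wraps the existing container heterogeneously.
        """
        if not 0 <= record.target_index < self.n_local_nodes:
            raise ValueError(
                f"target index {record.target_index} outside local node range"
                f" [0, {self.n_local_nodes})"
            )
        inner = self.table.get(source_gid)
        if inner is None:
            container = HomogeneousContainer(record.syn_id, self.k_cutoff)
            container.add(record)
            self.table.put(source_gid, container)
        elif isinstance(inner, HomogeneousContainer):
            if inner.syn_id == record.syn_id:
                inner.add(record)
            else:
                new_child = HomogeneousContainer(record.syn_id, self.k_cutoff)
                new_child.add(record)
                self.table.put(
                    source_gid, HeterogeneousContainer([inner, new_child])
                )
        else:
            inner.add(record, self.k_cutoff)

    def deliver(self, source_gid: int) -> list[ConnectionRecord]:
        """All records of ``source_gid``, each exactly once, in storage order."""
        inner = self.table.get(source_gid)
        if inner is None:
            return []
        return list(inner)

    def list_length_census(self) -> dict[str, int]:
        """Counts of sources with 0, 1, and >1 local records."""
        n_one = n_multi = 0
        for gid in self.table:
            n = len(self.table.get(gid))
            if n == 1:
                n_one += 1
            else:
                n_multi += 1
        return {
            "n_empty": self.table.n_gids - n_one - n_multi,
            "n_one": n_one,
            "n_multi": n_multi,
        }

    def container_census(self) -> dict[str, int]:
        census = {"fixed": 0, "growable": 0, "heterogeneous": 0}
        for gid in self.table:
            inner = self.table.get(gid)
            if isinstance(inner, HeterogeneousContainer):
                census["heterogeneous"] += 1
            elif inner.kind is StorageKind.GROWABLE:
                census["growable"] += 1
            else:
                census["fixed"] += 1
        return census

    def overhead_bytes(
        self,
        params: MemoryParams,
        syn_models: dict[int, str] | None = None,
    ) -> dict[str, float]:
        """Byte accounting against the memory-model parameters.

        Per source: 0 for an empty list, ``m1_c`` for a singleton, ``mgt1_c``
        otherwise.  Per record: the aligned object size of its synapse model
        (``syn_models`` maps syn_id to ``"static"``/``"stdp"``; default
        0 -> static, 1 -> stdp).
        """
        if syn_models is None:
            syn_models = {0: "static", 1: "stdp"}
        sizes = {
            sid: object_layout.synapse_layout(params.generation, model).total_bytes
            for sid, model in syn_models.items()
        }
        infra = objects = 0.0
        for gid in self.table:
            records = self.deliver(gid)
            infra += params.m1_c if len(records) == 1 else params.mgt1_c
            for rec in records:
                objects += sizes[rec.syn_id]
        return {"infrastructure": infra, "objects": objects, "total": infra + objects}


@dataclass(frozen=True)
class HandshakeResult:
    ok: bool
    failed_leg: str | None = None  # "synapse" or "target"

    def __bool__(self) -> bool:
        return self.ok


def handshake(
    source_emits: frozenset | set,
    synapse_handles: frozenset | set,
    target_handles: frozenset | set,
    event_kind: str,
) -> HandshakeResult:
    """Connection-time compatibility check without polymorphic synapses.

    The source sends a test event of ``event_kind`` (one of the kinds it
    emits, ``source_emits``) twice: once to a helper standing in for the
    synapse, once to the target node.  The connection is accepted only if
    both legs handle the event; the first failing leg is reported (mirroring
    the base-class handler that rejects by default).
    """
    if event_kind not in synapse_handles:
        return HandshakeResult(False, "synapse")
    if event_kind not in target_handles:
        return HandshakeResult(False, "target")
    return HandshakeResult(True)
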