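"""Alignment-aware struct layout and the packed delay/synapse-type word.

Reproduces the byte footprints of condensed synapse records on a 64-bit
architecture under natural alignment: every scalar field is aligned to its own
size and the struct is padded to a multiple of its widest member.  The packed
word stores the synaptic delay (in integer steps of the simulation resolution
``h``) in 24 bits and the synapse-type id in 8 bits, so delay and type together
cost 4 B instead of 8 B + 4 B.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FieldSpec",
    "StructLayout",
    "PackedDelayType",
    "layout",
    "synapse_catalog",
    "pack_delay_type",
    "unpack_delay_type",
    "index_fits_two_bytes",
    "MAX_DELAY_STEPS",
    "MAX_SYN_TYPES",
    "MAX_TWO_BYTE_INDEX",
]

MAX_DELAY_STEPS = 2**24  # delay field is 24 bits wide
MAX_SYN_TYPES = 2**8  # synapse-type id field is 8 bits wide
MAX_TWO_BYTE_INDEX = 2**16 - 1  # largest thread-local index addressable in 2 B


@dataclass(frozen=True)
class FieldSpec:
    """One scalar member of a record: name, size and alignment in bytes."""

    name: str
    size_bytes: int
    alignment_bytes: int

    def __post_init__(self) -> None:
        if self.size_bytes < 1:
            raise ValueError(f"field {self.name!r}: size must be >= 1")
        a = self.alignment_bytes
        if a < 1 or (a & (a - 1)) != 0:
            raise ValueError(f"field {self.name!r}: alignment must be a power of two")


@dataclass(frozen=True)
class StructLayout:
    """Resolved layout: per-field offsets, total size and inserted padding."""

    fields: tuple[FieldSpec, ...]
    offsets: tuple[int, ...]
    total_bytes: int
    padding_bytes: int

    @property
    def data_bytes(self) -> int:
        return self.total_bytes - self.padding_bytes

    @property
    def data_fraction(self) -> float:
        return self.data_bytes / self.total_bytes

    def as_dict(self) -> dict:
        return {
            "fields": [
                {"name": f.name, "size": f.size_bytes, "align": f.alignment_bytes, "offset": o}
                for f, o in zip(self.fields, self.offsets)
            ],
            "total_bytes": self.total_bytes,
            "padding_bytes": self.padding_bytes,
            "data_bytes": self.data_bytes,
        }


def layout(fields: list[FieldSpec] | tuple[FieldSpec, ...]) -> StructLayout:
    """Assign sequential offsets to ``fields`` without reordering.

    Each field is placed at the next offset that is a multiple of its
    alignment; the struct size is rounded up to a multiple of the maximum
    field alignment (so arrays of the struct stay aligned).
    """
    if not fields:
        raise ValueError("cannot lay out an empty field list")
    offsets: list[int] = []
    cursor = 0
    for f in fields:
        a = f.alignment_bytes
        cursor = (cursor + a - 1) // a * a
        offsets.append(cursor)
        cursor += f.size_bytes
    max_align = max(f.alignment_bytes for f in fields)
    total = (cursor + max_align - 1) // max_align * max_align
    padding = total - sum(f.size_bytes for f in fields)
    return StructLayout(tuple(fields), tuple(offsets), total, padding)


# Field catalogs of the synapse records. 3g stores the target as a full
# 8 B pointer, an 8 B long delay, and a 4 B type id; 4g replaces these by a
# 2 B thread-local index and the 4 B packed delay+type word. The exact 3g
# field order is a convention; the 32 B result is order-invariant here.
_CATALOG: dict[tuple[str, str], tuple[tuple[str, int, int], ...]] = {
    ("3g", "static"): (
        ("syn_type", 4, 4),
        ("target_ptr", 8, 8),
        ("delay", 8, 8),
        ("weight", 8, 8),
    ),
    ("3g", "stdp"): (
        ("syn_type", 4, 4),
        ("target_ptr", 8, 8),
        ("delay", 8, 8),
        ("weight", 8, 8),
        ("trace", 8, 8),
    ),
    ("4g", "static"): (
        ("target_index", 2, 2),
        ("delay_syn_id", 4, 4),
        ("weight", 8, 8),
    ),
    ("4g", "stdp"): (
        ("target_index", 2, 2),
        ("delay_syn_id", 4, 4),
        ("weight", 8, 8),
        ("trace", 8, 8),
    ),
}


def synapse_catalog(generation: str, model: str) -> list[FieldSpec]:
    """Ordered field list of a synapse record for a kernel generation.

    ``generation`` is ``"3g"`` or ``"4g"``; ``model`` is ``"static"`` or
    ``"stdp"``.
    """
    try:
        fields = _CATALOG[(generation, model)]
    except KeyError:
        raise ValueError(f"unknown synapse record {generation!r}/{model!r}") from None
    return [FieldSpec(name, size, align) for name, size, align in fields]


def synapse_layout(generation: str, model: str) -> StructLayout:
    """Convenience: :func:`layout` applied to :func:`synapse_catalog`."""
    return layout(synapse_catalog(generation, model))


@dataclass(frozen=True)
class PackedDelayType:
    """Delay (24-bit, in steps of ``h``) and synapse-type id (8-bit)."""

    delay_steps: int
    syn_id: int

    def __post_init__(self) -> None:
        if not 0 <= self.delay_steps < MAX_DELAY_STEPS:
            raise ValueError(f"delay_steps {self.delay_steps} outside [0, 2^24)")
        if not 0 <= self.syn_id < MAX_SYN_TYPES:
            raise ValueError(f"syn_id {self.syn_id} outside [0, 256)")


def pack_delay_type(delay_steps: int, syn_id: int) -> int:
    """Pack delay and synapse type into one 4-byte word (delay in low bits)."""
    p = PackedDelayType(delay_steps, syn_id)  # range validation
    return p.delay_steps | (p.syn_id << 24)


def unpack_delay_type(word: int) -> tuple[int, int]:
    """Inverse of :func:`pack_delay_type`: returns ``(delay_steps, syn_id)``."""
    if not 0 <= word < 2**32:
        raise ValueError(f"word {word} is not a 4-byte value")
    return word & (MAX_DELAY_STEPS - 1), word >> 24


def index_fits_two_bytes(n_local_nodes: int) -> bool:
    """Whether every thread-local index fits the 2 B addressing scheme.

    Indexed target addressing replaces the 8 B target pointer by the
    position of the target in the vector of VP-local nodes; it is valid
    only while that vector holds at most 65,535 nodes.
    """
    return n_local_nodes <= MAX_TWO_BYTE_INDEX
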