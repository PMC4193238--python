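"""Plain-text writers/readers: gdf spike rasters and JSON/CSV reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .memory_model import MemoryBreakdown
from .simulator import SimResult

__all__ = [
    "write_gdf",
    "read_gdf",
    "write_json",
    "breakdown_to_frame",
    "write_breakdown_csv",
]


def write_gdf(path: str | Path, result: SimResult) -> None:
    """Write spikes as two-column plain text: sender GID, time in ms."""
    with open(path, "w") as fh:
        for gid, t in zip(result.spike_senders, result.spike_times):
            fh.write(f"{int(gid)}\t{t:.3f}\n")


def read_gdf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a gdf raster back as ``(senders, times_ms)``."""
    text = Path(path).read_text()
    if not text.strip():
        return np.empty(0, dtype=np.int64), np.empty(0)
    data = np.loadtxt(path, ndmin=2)
    return data[:, 0].astype(np.int64), data[:, 1]


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def breakdown_to_frame(breakdown: MemoryBreakdown) -> pd.DataFrame:
    """One-row DataFrame of the per-process memory components (bytes)."""
    return pd.DataFrame([breakdown.as_dict()])


def write_breakdown_csv(path: str | Path, breakdown: MemoryBreakdown) -> None:
    breakdown_to_frame(breakdown).to_csv(path, index=False)
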