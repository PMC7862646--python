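"""Reading contact event lists and building windowed snapshot series.

The input format is the SocioPatterns "tij" plain-text distribution: one
contact event per line, whitespace-separated ``t i j`` with ``t`` in seconds
(20-s resolution in the RFID deployments) and ``i``, ``j`` opaque node
identifiers.  Events are aggregated into fixed-width half-open windows
``[origin + k*width, origin + (k+1)*width)``; within a window an edge exists
for every unordered pair with at least ``min_events`` events, ``N_t`` counts
nodes incident to at least one edge and ``M_t`` the distinct pairs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import SnapshotSeries

__all__ = [
    "ContactEvent",
    "WindowingSpec",
    "read_contacts",
    "build_snapshot_series",
    "write_series",
    "read_series",
    "write_table",
    "read_table",
]


@dataclass(frozen=True, order=True)
class ContactEvent:
    """One recorded proximity event between two distinct nodes."""

    t: int
    i: str
    j: str

    def pair(self) -> tuple[str, str]:
        return (self.i, self.j) if self.i <= self.j else (self.j, self.i)


@dataclass(frozen=True)
class WindowingSpec:
    """How to aggregate events into snapshots.

    ``origin=None`` anchors at the first event timestamp floored to a multiple
    of ``width``.  ``time_range`` restricts to ``[start, end)`` before
    windowing (e.g. one conference day).  ``drop_empty=True`` removes windows
    with no events (overnight gaps) instead of reporting them as (0, 0).
    """

    width: float = 600.0
    origin: float | None = None
    drop_empty: bool = True
    time_range: tuple[float, float] | None = None
    min_events: int = 1

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")


def read_contacts(path, dialect: str = "tij") -> list[ContactEvent]:
    """Parse a tij file (gzip accepted) into time-sorted events.

    ``dialect="tij"`` requires exactly three columns; ``"tij_meta"`` uses the
    first three of at least three (SocioPatterns files with trailing metadata
    columns).  Malformed lines and self-contacts raise with the line number.
    """
    if dialect not in ("tij", "tij_meta"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    events = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3 or (dialect == "tij" and len(parts) != 3):
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                t = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from exc
            i, j = parts[1], parts[2]
            if i == j:
                raise ValueError(f"{path}:{lineno}: self-contact {i!r}")
            events.append(ContactEvent(t=t, i=i, j=j))
    events.sort(key=lambda e: e.t)
    return events


def build_snapshot_series(events: Sequence[ContactEvent],
                          windowing: WindowingSpec | None = None) -> SnapshotSeries:
    """Aggregate events into a per-window (N_t, M_t) series."""
    if windowing is None:
        windowing = WindowingSpec()
    events = sorted(events, key=lambda e: e.t)
    if windowing.time_range is not None:
        lo, hi = windowing.time_range
        events = [e for e in events if lo <= e.t < hi]
    if not events:
        raise ValueError("no contact events to window")
    width = windowing.width
    origin = windowing.origin
    if origin is None:
        origin = np.floor(events[0].t / width) * width
    buckets: dict[int, list] = {}
    for e in events:
        if e.t < origin:
            raise ValueError(f"event at t={e.t} precedes window origin {origin}")
        k = int((e.t - origin) // width)
        buckets.setdefault(k, []).append(e.pair())
    last = max(buckets)
    starts, ns, ms = [], [], []
    for k in range(last + 1):
        pairs = buckets.get(k, [])
        if windowing.min_events > 1:
            counts = pd.Series(pairs).value_counts() if pairs else pd.Series(dtype=int)
            edge_set = set(counts[counts >= windowing.min_events].index)
        else:
            edge_set = set(pairs)
        if not edge_set and windowing.drop_empty:
            continue
        nodes = {x for pair in edge_set for x in pair}
        starts.append(origin + k * width)
        ns.append(len(nodes))
        ms.append(len(edge_set))
    return SnapshotSeries(window_start=np.array(starts),
                          n_active=np.array(ns), m_edges=np.array(ms))


def write_series(path, series: SnapshotSeries) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> SnapshotSeries:
    df = pd.read_csv(path)
    return SnapshotSeries.from_frame(df)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in {path}: {sorted(missing)}")
    return df
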