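"""Per-window observation container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SnapshotSeries"]


@dataclass(frozen=True)
class SnapshotSeries:
    """Observed per-window counts D_t = (N_t, M_t).

    Attributes
    ----------
    window_start
        Start of each aggregation window (seconds since the data origin).
    n_active
        Number of nodes with at least one edge in the window.
    m_edges
        Number of distinct edges (unordered node pairs in contact) in the window.
    """

    window_start: np.ndarray
    n_active: np.ndarray
    m_edges: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "window_start", np.asarray(self.window_start, dtype=float))
        object.__setattr__(self, "n_active", np.asarray(self.n_active, dtype=np.int64))
        object.__setattr__(self, "m_edges", np.asarray(self.m_edges, dtype=np.int64))
        t, n, m = self.window_start, self.n_active, self.m_edges
        if not (t.shape == n.shape == m.shape) or t.ndim != 1:
            raise ValueError("window_start, n_active and m_edges must be aligned 1-d arrays")
        if np.any(n < 0) or np.any(m < 0):
            raise ValueError("counts must be non-negative")
        if np.any((n == 0) != (m == 0)):
            raise ValueError("N_t == 0 must hold exactly when M_t == 0")
        if np.any(m > n * (n - 1) // 2):
            raise ValueError("M_t exceeds the complete-graph bound N_t(N_t-1)/2")

    def __len__(self) -> int:
        return self.window_start.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_start": self.window_start, "N": self.n_active, "M": self.m_edges}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnapshotSeries":
        missing = {"window_start", "N", "M"} - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        return cls(
            window_start=df["window_start"].to_numpy(),
            n_active=df["N"].to_numpy(),
            m_edges=df["M"].to_numpy(),
        )
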