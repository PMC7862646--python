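"""Generative simulator for regime-switching temporal contact networks.

Validation-style synthetic data: a two-state Markov chain selects, window by
window, whether the population ``N_p`` (Regime 1) or the overall activity
``kappa`` (Regime 2) is the time-varying parameter.  The active parameter
decays geometrically (default factor 0.95 per window) while the other resets
to its base value; each window's snapshot is then realised from the
hidden-variable model: activities Uniform[0, 1], each unordered pair an
independent Bernoulli with probability ``kappa_t * a_i * a_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .series import SnapshotSeries

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "sample_state_sequence",
    "evolve_latent_parameters",
    "sample_snapshot",
    "simulate_series",
    "to_tij",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic run.

    ``p11``/``p22`` are the per-window probabilities of *staying* in Regime 1
    / Regime 2; ``decay`` multiplies the active latent parameter each window;
    ``init_p1`` is the probability that the first window is in Regime 1.
    ``redraw_activities=False`` keeps one activity vector per node for the
    whole run instead of redrawing each window.
    """

    n_potential_base: int = 200
    kappa_base: float = 0.3
    p11: float = 0.95
    p22: float = 0.95
    decay: float = 0.95
    n_windows: int = 200
    init_p1: float = 0.5
    seed: int = 0
    redraw_activities: bool = True
    window_width: float = 600.0

    def __post_init__(self):
        if not (self.n_potential_base >= 2):
            raise ValueError("n_potential_base must be an integer >= 2")
        if not (0 < self.kappa_base <= 1):
            raise ValueError("kappa_base must lie in (0, 1]")
        for name in ("p11", "p22", "init_p1"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated series plus the ground truth that produced it."""

    states: np.ndarray          # S_t in {1, 2}
    np_path: np.ndarray         # true N_p,t (real-valued; decay not rounded)
    kappa_path: np.ndarray      # true kappa_t
    series: SnapshotSeries
    seed: int
    edge_lists: Optional[list] = None  # per-window list of (i, j) pairs, if kept


def sample_state_sequence(p11, p22, n_windows, init_p1=0.5, rng=None):
    """Draw a two-state Markov path; 1 = population-driven, 2 = activity-driven."""
    if not (0 <= p11 <= 1 and 0 <= p22 <= 1 and 0 <= init_p1 <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(rng)
    states = np.empty(n_windows, dtype=np.int64)
    states[0] = 1 if rng.random() < init_p1 else 2
    u = rng.random(n_windows - 1)
    for t in range(1, n_windows):
        stay = p11 if states[t - 1] == 1 else p22
        states[t] = states[t - 1] if u[t - 1] < stay else 3 - states[t - 1]
    return states


def evolve_latent_parameters(states, n_potential_base, kappa_base, decay=0.95):
    """Latent parameter paths implied by a state sequence.

    In a Regime-1 window the population decays from its previous value and the
    activity resets to base; in a Regime-2 window the roles swap.  The value
    preceding the first window is the base for both parameters, so the decay
    already applies in the first window of a run.
    """
    states = np.asarray(states)
    np_path = np.empty(states.size, dtype=float)
    kappa_path = np.empty(states.size, dtype=float)
    prev_np, prev_kappa = float(n_potential_base), float(kappa_base)
    for t, s in enumerate(states):
        if s == 1:
            np_path[t] = decay * prev_np
            kappa_path[t] = kappa_base
        elif s == 2:
            kappa_path[t] = decay * prev_kappa
            np_path[t] = n_potential_base
        else:
            raise ValueError(f"invalid state {s!r} at window {t}")
        prev_np, prev_kappa = np_path[t], kappa_path[t]
    return np_path, kappa_path


def sample_snapshot(n_potential, kappa, rng=None, activities=None, return_edges=False):
    """Realise one snapshot; returns ``(n_active, m_edges)``.

    ``n_potential`` is rounded to the nearest integer >= 1.  ``activities`` may
    be supplied (node-persistent mode); otherwise a fresh Uniform[0, 1] vector
    is drawn.
    """
    rng = np.random.default_rng(rng)
    n = max(1, int(round(float(n_potential))))
    if not (0 < kappa <= 1):
        raise ValueError("kappa must lie in (0, 1]")
    if n == 1:
        return ((0, 0, []) if return_edges else (0, 0))
    a = rng.random(n) if activities is None else np.asarray(activities, dtype=float)[:n]
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < kappa * a[iu] * a[ju]
    m = int(hit.sum())
    active = np.zeros(n, dtype=bool)
    active[iu[hit]] = True
    active[ju[hit]] = True
    n_active = int(active.sum())
    if return_edges:
        return n_active, m, list(zip(iu[hit].tolist(), ju[hit].tolist()))
    return n_active, m


def simulate_series(config: SimConfig, keep_edges: bool = False) -> SyntheticDataset:
    """Full run: Markov states -> latent paths -> per-window snapshots."""
    rng = np.random.default_rng(config.seed)
    states = sample_state_sequence(
        config.p11, config.p22, config.n_windows, config.init_p1, rng
    )
    np_path, kappa_path = evolve_latent_parameters(
        states, config.n_potential_base, config.kappa_base, config.decay
    )
    persistent = None
    if not config.redraw_activities:
        persistent = rng.random(config.n_potential_base)
    n_obs = np.empty(config.n_windows, dtype=np.int64)
    m_obs = np.empty(config.n_windows, dtype=np.int64)
    edge_lists = [] if keep_edges else None
    for t in range(config.n_windows):
        out = sample_snapshot(
            np_path[t], kappa_path[t], rng,
            activities=persistent, return_edges=keep_edges,
        )
        if keep_edges:
            n_obs[t], m_obs[t], edges = out
            edge_lists.append(edges)
        else:
            n_obs[t], m_obs[t] = out
    series = SnapshotSeries(
        window_start=np.arange(config.n_windows) * config.window_width,
        n_active=n_obs,
        m_edges=m_obs,
    )
    return SyntheticDataset(
        states=states, np_path=np_path, kappa_path=kappa_path,
        series=series, seed=config.seed, edge_lists=edge_lists,
    )


def to_tij(dataset: SyntheticDataset, tick: float = 20.0) -> str:
    """Render a simulated run as SocioPatterns-style "t i j" text.

    Each edge in window ``t`` is written once, at the window's first tick.
    Requires the dataset to have been simulated with ``keep_edges=True``.
    """
    if dataset.edge_lists is None:
        raise ValueError("dataset was simulated without keep_edges=True")
    lines = []
    for t, edges in enumerate(dataset.edge_lists):
        stamp = int(dataset.series.window_start[t] // tick * tick)
        for i, j in edges:
            lines.append(f"{stamp} {i} {j}")
    return "\n".join(lines) + ("\n" if lines else "")
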