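"""Closed-form moments of the dynamic hidden-variable contact model.

A snapshot network over ``N_p`` potential individuals is generated by giving
each node an intrinsic activity ``a_i ~ Uniform[0, 1]`` and connecting each
unordered pair independently with probability ``kappa * a_i * a_j``, where
``kappa`` is a global activity modulator.  Averaging over activities yields
closed forms for the isolated-node fraction ``q0``, the expected numbers of
active nodes ``N`` and edges ``M``, the mean degree and the density, together
with the two one-parameter "regime" curves in the (M, N) plane:

* Regime 1 (population-driven): ``kappa`` fixed, ``N_p`` varies; the curve
  ``h1(M; kappa)`` traces N against M as the population changes.
* Regime 2 (activity-driven): ``N_p`` fixed, ``kappa`` varies; the curve
  ``h2(M; N_p)`` traces N against M as the overall activity changes.

``N_p`` is treated as a continuous real >= 1 throughout: the inverse map from
an observed edge count returns non-integers, and the switching likelihood is
evaluated at such values.  Only the simulator rounds populations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "edge_probability",
    "isolated_fraction",
    "expected_active_nodes",
    "expected_edges",
    "mean_degree",
    "expected_density",
    "invert_population",
    "invert_activity",
    "regime1_curve",
    "regime2_curve",
]


def _check_kappa(kappa) -> None:
    # base 1 - kappa/2 must stay >= 0 for real exponents N_p
    if np.any(np.asarray(kappa) <= 0) or np.any(np.asarray(kappa) > 2):
        raise ValueError(f"kappa must lie in (0, 2], got {kappa!r}")


def _check_np(n_potential) -> None:
    if np.any(np.asarray(n_potential) < 1):
        raise ValueError(f"n_potential must be >= 1, got {n_potential!r}")


def edge_probability(kappa, a_i, a_j):
    """Probability that two nodes with activities ``a_i``, ``a_j`` share an edge.

    ``P = kappa * a_i * a_j``; activities must lie in [0, 1] and kappa in (0, 1]
    so that the product is a valid probability.
    """
    kappa = np.asarray(kappa, dtype=float)
    a_i = np.asarray(a_i, dtype=float)
    a_j = np.asarray(a_j, dtype=float)
    if np.any(kappa <= 0) or np.any(kappa > 1):
        raise ValueError("kappa must lie in (0, 1]")
    for a in (a_i, a_j):
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("activities must lie in [0, 1]")
    return kappa * a_i * a_j


def _pow_base(kappa, n_potential):
    """(1 - kappa/2) ** n_potential, stable for large real n_potential."""
    base = 1.0 - np.asarray(kappa, dtype=float) / 2.0
    npot = np.asarray(n_potential, dtype=float)
    # exp(n * log base); base == 0 (kappa == 2) gives 0 for n >= 1
    with np.errstate(divide="ignore"):
        logb = np.log(base)
    out = np.where(base > 0, np.exp(npot * logb), 0.0)
    return out


def isolated_fraction(kappa, n_potential):
    """Expected fraction ``q0`` of the potential population with no edge.

    ``q0 = (2 / (kappa * N_p)) * (1 - (1 - kappa/2)**N_p)``.
    """
    _check_kappa(kappa)
    _check_np(n_potential)
    kappa = np.asarray(kappa, dtype=float)
    npot = np.asarray(n_potential, dtype=float)
    q0 = 2.0 / (kappa * npot) * (1.0 - _pow_base(kappa, npot))
    return np.clip(q0, 0.0, 1.0)[()] if np.ndim(q0) == 0 else np.clip(q0, 0.0, 1.0)


def expected_active_nodes(kappa, n_potential):
    """Expected number N of nodes with at least one edge: ``(1 - q0) * N_p``."""
    npot = np.asarray(n_potential, dtype=float)
    return npot * (1.0 - isolated_fraction(kappa, n_potential))


def expected_edges(kappa, n_potential):
    """Expected number of edges ``M = kappa * N_p * (N_p - 1) / 8``."""
    _check_kappa(kappa)
    _check_np(n_potential)
    kappa = np.asarray(kappa, dtype=float)
    npot = np.asarray(n_potential, dtype=float)
    return kappa * npot * (npot - 1.0) / 8.0


def mean_degree(kappa, n_potential):
    """Mean degree over all ``N_p`` nodes (isolated included): ``kappa * (N_p - 1) / 4``."""
    _check_kappa(kappa)
    _check_np(n_potential)
    kappa = np.asarray(kappa, dtype=float)
    npot = np.asarray(n_potential, dtype=float)
    return kappa * (npot - 1.0) / 4.0


def expected_density(kappa, n_potential):
    """Expected density ``2M / (N (N - 1))`` of the active subgraph.

    Evaluated through the identity
    ``(kappa / 4) * (1 / (1 - q0))**2 * (1 + q0 / (N - 1))``,
    which is algebraically equal to forming 2M/(N(N-1)) from the closed-form
    moments.  As ``N_p -> inf`` at fixed kappa the density tends to kappa/4.
    """
    n = expected_active_nodes(kappa, n_potential)
    if np.any(np.asarray(n) <= 1):
        raise ValueError("expected N must exceed 1 for the density to be defined")
    q0 = isolated_fraction(kappa, n_potential)
    kappa = np.asarray(kappa, dtype=float)
    return kappa / 4.0 * (1.0 / (1.0 - q0)) ** 2 * (1.0 + q0 / (n - 1.0))


def invert_population(m_edges, kappa):
    """Potential population implied by an edge count at fixed activity.

    Inverse of :func:`expected_edges` in ``N_p``:
    ``N_p(M, kappa) = (1 + sqrt(1 + 32 M / kappa)) / 2``; returns a real >= 1.
    """
    _check_kappa(kappa)
    m = np.asarray(m_edges, dtype=float)
    if np.any(m < 0):
        raise ValueError("m_edges must be >= 0")
    kappa = np.asarray(kappa, dtype=float)
    return (1.0 + np.sqrt(1.0 + 32.0 * m / kappa)) / 2.0


def invert_activity(m_edges, n_potential):
    """Activity modulator implied by an edge count at fixed population.

    Inverse of :func:`expected_edges` in ``kappa``:
    ``kappa(M, N_p) = 8 M / (N_p (N_p - 1))``.  The raw value is returned even
    if it exceeds 1 (physically inconsistent inputs); callers decide validity.
    """
    m = np.asarray(m_edges, dtype=float)
    npot = np.asarray(n_potential, dtype=float)
    if np.any(m < 0):
        raise ValueError("m_edges must be >= 0")
    if np.any(npot <= 1):
        raise ValueError("n_potential must exceed 1")
    return 8.0 * m / (npot * (npot - 1.0))


def regime1_curve(m_edges, kappa):
    """Population-driven scaling curve ``h1(M; kappa)``.

    Expected N when the observed M is attributed entirely to a time-varying
    population at fixed kappa.  Strictly increasing in M; h1(0) = 0.
    """
    npot = invert_population(m_edges, kappa)
    return expected_active_nodes(kappa, npot)


def regime2_curve(m_edges, n_potential):
    """Activity-driven scaling curve ``h2(M; N_p)``.

    Expected N when the observed M is attributed entirely to a time-varying
    activity at fixed population.  Bounded above by ``N_p``.  Raises if the
    implied kappa exceeds 2, where the closed form leaves the real domain;
    implied kappa in (1, 2] is evaluated and left to the caller's error model.
    """
    kappa = invert_activity(m_edges, n_potential)
    zero = np.asarray(m_edges, dtype=float) == 0
    if np.all(zero):
        return np.zeros_like(np.asarray(kappa, dtype=float))[()] if np.ndim(kappa) == 0 else np.zeros_like(kappa)
    _check_kappa(np.where(zero, 1.0, kappa))
    n = expected_active_nodes(np.where(zero, 1.0, kappa), n_potential)
    n = np.where(zero, 0.0, n)
    return n[()] if np.ndim(n) == 0 else n
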