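"""Exact state-probability recursions for the two-regime switching model.

Observation model: at each window the observed active-node count ``N_t`` is
Gaussian around the regime curve evaluated at the observed edge count,

    N_t | S_t = 1  ~  Normal(h1(M_t; kappa), sigma1)
    N_t | S_t = 2  ~  Normal(h2(M_t; N_p),  sigma2)

with the hidden regime ``S_t`` following a two-state Markov chain with stay
probabilities ``p11``, ``p22``.  The Hamilton filter gives the one-step-ahead
(predicted) and filtered state probabilities together with the exact
log-likelihood; the Kim smoother turns those into full-sample (smoothed)
probabilities.  ``brute_force_state_posterior`` enumerates all ``2**T`` state
paths and is the test oracle for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model
from .series import SnapshotSeries

__all__ = [
    "ThetaParams",
    "FilterSmootherResult",
    "FilterError",
    "regime_conditional_density",
    "hamilton_filter",
    "kim_smoother",
    "filter_smoother",
    "brute_force_state_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class FilterError(RuntimeError):
    """Raised when the recursion degenerates (all observation densities zero)."""


@dataclass(frozen=True)
class ThetaParams:
    """Constant parameter vector theta = {N_p, kappa, sigma1, sigma2, p11, p22}."""

    n_potential: float
    kappa: float
    sigma1: float
    sigma2: float
    p11: float
    p22: float

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("residual standard deviations must be positive")
        # 1 is allowed: a degenerate absorbing chain is still well defined
        if not (0 < self.p11 <= 1 and 0 < self.p22 <= 1):
            raise ValueError("stay probabilities must lie in (0, 1]")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must lie in (0, 1]")
        if self.n_potential <= 1:
            raise ValueError("n_potential must exceed 1")

    @property
    def transition_matrix(self) -> np.ndarray:
        """P[r, s] = Pr(S_t = s+1 | S_{t-1} = r+1)."""
        return np.array(
            [[self.p11, 1.0 - self.p11], [1.0 - self.p22, self.p22]]
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.n_potential, self.kappa, self.sigma1, self.sigma2, self.p11, self.p22]
        )

    @classmethod
    def from_array(cls, x) -> "ThetaParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class FilterSmootherResult:
    """Predicted, filtered and (optionally) smoothed probability pairs.

    Rows index windows; column 0 is Regime 1 (population-driven), column 1 is
    Regime 2 (activity-driven).  ``predicted[t]`` conditions on observations
    up to ``t-1``, ``filtered[t]`` on observations up to ``t``, ``smoothed[t]``
    on the whole series.
    """

    predicted: np.ndarray
    filtered: np.ndarray
    loglik: float
    smoothed: np.ndarray | None = None


def regime_log_densities(series: SnapshotSeries, theta: ThetaParams) -> np.ndarray:
    """T x 2 matrix of log f(D_t | S_t = s) for s in {1, 2}."""
    m = series.m_edges.astype(float)
    n = series.n_active.astype(float)
    h1 = model.regime1_curve(m, theta.kappa)
    h2 = model.regime2_curve(m, theta.n_potential)
    out = np.empty((len(series), 2))
    for col, (h, sig) in enumerate(((h1, theta.sigma1), (h2, theta.sigma2))):
        out[:, col] = -0.5 * (_LOG_2PI + 2.0 * np.log(sig)) - (n - h) ** 2 / (2.0 * sig ** 2)
    return out


def regime_conditional_density(d_t, s: int, theta: ThetaParams) -> float:
    """Gaussian observation density of one window given the regime.

    ``d_t`` is the pair ``(N_t, M_t)``; ``s`` is 1 or 2.
    """
    if s not in (1, 2):
        raise ValueError("state must be 1 or 2")
    n_t, m_t = float(d_t[0]), float(d_t[1])
    if s == 1:
        h = model.regime1_curve(m_t, theta.kappa)
        sig = theta.sigma1
    else:
        h = model.regime2_curve(m_t, theta.n_potential)
        sig = theta.sigma2
    return float(np.exp(-0.5 * (_LOG_2PI + 2.0 * np.log(sig)) - (n_t - h) ** 2 / (2.0 * sig ** 2)))


def _init_probs(init_probs, theta: ThetaParams) -> np.ndarray:
    if init_probs is None:
        return np.array([0.5, 0.5])
    if isinstance(init_probs, str):
        if init_probs == "stationary":
            p12, p21 = 1.0 - theta.p11, 1.0 - theta.p22
            pi1 = p21 / (p12 + p21)
            return np.array([pi1, 1.0 - pi1])
        raise ValueError(f"unknown init_probs spec {init_probs!r}")
    pi = np.asarray(init_probs, dtype=float)
    if pi.shape != (2,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("init_probs must be a probability pair")
    return pi


def hamilton_filter(series: SnapshotSeries, theta: ThetaParams,
                    init_probs=None) -> FilterSmootherResult:
    """Forward recursion: predicted and filtered probabilities plus log-likelihood.

    Each step propagates the filtered distribution through the transition
    matrix and reweights by the regime observation densities; the
    log-likelihood accumulates the log of the per-window normalising constant.
    The update is performed on rescaled (max-subtracted) log densities, so it
    is stable where a naive linear-scale implementation would underflow.
    """
    if len(series) < 1:
        raise ValueError("series must contain at least one window")
    pi = _init_probs(init_probs, theta)
    P = theta.transition_matrix
    logf = regime_log_densities(series, theta)
    T = len(series)
    predicted = np.empty((T, 2))
    filtered = np.empty((T, 2))
    loglik = 0.0
    xi = pi
    for t in range(T):
        pred = P.T @ xi
        predicted[t] = pred
        c = logf[t].max()
        if not np.isfinite(c):
            raise FilterError(
                f"all regime densities vanish at window {t} "
                f"(D_t = ({series.n_active[t]}, {series.m_edges[t]}))"
            )
        w = pred * np.exp(logf[t] - c)
        norm = w.sum()
        if norm <= 0 or not np.isfinite(norm):
            raise FilterError(f"filter degenerated at window {t}")
        filtered[t] = w / norm
        loglik += c + np.log(norm)
        xi = filtered[t]
    return FilterSmootherResult(predicted=predicted, filtered=filtered, loglik=float(loglik))


def kim_smoother(filter_result: FilterSmootherResult,
                 transition_matrix: np.ndarray) -> np.ndarray:
    """Backward fixed-interval recursion for smoothed probabilities.

    ``xi_{t|T} = xi_{t|t} * (P @ (xi_{t+1|T} / xi_{t+1|t}))`` element-wise,
    initialised with ``xi_{T|T}`` equal to the last filtered pair.
    """
    P = np.asarray(transition_matrix, dtype=float)
    filtered = filter_result.filtered
    predicted = filter_result.predicted
    T = filtered.shape[0]
    smoothed = np.empty_like(filtered)
    smoothed[-1] = filtered[-1]
    for t in range(T - 2, -1, -1):
        pred = predicted[t + 1]
        if np.any(pred <= 0):
            raise FilterError(f"zero predicted probability at window {t + 1}")
        smoothed[t] = filtered[t] * (P @ (smoothed[t + 1] / pred))
        smoothed[t] /= smoothed[t].sum()
    return smoothed


def filter_smoother(series: SnapshotSeries, theta: ThetaParams,
                    init_probs=None) -> FilterSmootherResult:
    """Run the filter and smoother in one call."""
    res = hamilton_filter(series, theta, init_probs)
    smoothed = kim_smoother(res, theta.transition_matrix)
    return FilterSmootherResult(
        predicted=res.predicted, filtered=res.filtered,
        loglik=res.loglik, smoothed=smoothed,
    )


def brute_force_state_posterior(series: SnapshotSeries, theta: ThetaParams,
                                init_probs=None, max_windows: int = 15):
    """Exact marginals and log-likelihood by enumerating all 2**T state paths.

    Test oracle only; refuses series longer than ``max_windows``.
    Returns ``(marginals, loglik)`` with ``marginals`` a T x 2 array.
    """
    T = len(series)
    if T > max_windows:
        raise ValueError(f"enumeration over 2**{T} paths refused (T > {max_windows})")
    pi = _init_probs(init_probs, theta)
    P = theta.transition_matrix
    logf = regime_log_densities(series, theta)
    # init_probs is the pre-sample state distribution, as in the filter:
    # the first window's prior is one transition ahead of it
    log_pi = np.log(P.T @ pi)
    with np.errstate(divide="ignore"):
        log_P = np.log(P)
    log_weights = np.empty(2 ** T)
    paths = np.empty((2 ** T, T), dtype=np.int64)
    for idx in range(2 ** T):
        path = [(idx >> t) & 1 for t in range(T)]
        lw = log_pi[path[0]] + logf[0, path[0]]
        for t in range(1, T):
            lw += log_P[path[t - 1], path[t]] + logf[t, path[t]]
        log_weights[idx] = lw
        paths[idx] = path
    c = log_weights.max()
    w = np.exp(log_weights - c)
    total = w.sum()
    loglik = c + np.log(total)
    marginals = np.empty((T, 2))
    for t in range(T):
        marginals[t, 1] = w[paths[:, t] == 1].sum() / total
        marginals[t, 0] = 1.0 - marginals[t, 1]
    return marginals, float(loglik)
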