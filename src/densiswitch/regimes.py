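"""Posterior regime probabilities, window classification and parameter paths.

Given MCMC draws of the constant parameter vector, each draw induces smoothed
regime probabilities ``Pr(S_t = 1 | psi_T; theta^(m))`` through the
filter/smoother.  A window is labelled

* Regime 1 (population-driven) if more than ``frac_threshold`` (default 95%)
  of draws put that probability above ``prob_threshold`` (default 0.5),
* Regime 2 (activity-driven) in the symmetric case,
* "gray" otherwise — the draws straddle the cut and no mechanism dominates.

The time-varying parameter paths mix the two regime-conditional estimates by
the smoothed probability:

    Np_hat_t   = Pr(S_t=1) * Np(M_t; kappa_hat) + Pr(S_t=2) * Np_hat
    kappa_hat_t = Pr(S_t=1) * kappa_hat + Pr(S_t=2) * kappa(M_t; Np_hat)

with credible bands from evaluating the same expressions per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .filtering import FilterError, ThetaParams, filter_smoother
from .inference import PosteriorSamples
from .series import SnapshotSeries

__all__ = [
    "RegimeClassification",
    "ParameterPaths",
    "smoothed_prob_draws",
    "classify_windows",
    "parameter_paths",
    "density_report",
    "classify_series",
    "classification_table",
]

LABELS = ("regime1", "regime2", "gray")


@dataclass(frozen=True)
class RegimeClassification:
    """Per-window labels plus the per-draw probability matrix behind them."""

    labels: np.ndarray            # dtype=object strings from LABELS
    prob_draws: np.ndarray        # (n_draws_used, T) of Pr(S_t=1 | psi_T)
    prob_threshold: float = 0.5
    frac_threshold: float = 0.95


@dataclass(frozen=True)
class ParameterPaths:
    """Point paths and central 95% bands for N_p,t and kappa_t."""

    np_hat: np.ndarray
    np_lo: np.ndarray
    np_hi: np.ndarray
    kappa_hat: np.ndarray
    kappa_lo: np.ndarray
    kappa_hi: np.ndarray


def smoothed_prob_draws(samples: PosteriorSamples, series: SnapshotSeries,
                        init_probs=None, thin: int = 1) -> np.ndarray:
    """Pr(S_t = 1 | psi_T; theta^(m)) for every kept draw (optionally thinned).

    Returns a (n_used_draws, T) matrix; draws whose filter degenerates are
    dropped with a warning flag row of NaN (none occur in practice because the
    posterior support excludes them).
    """
    pooled = samples.pooled()[::max(1, int(thin))]
    out = np.empty((pooled.shape[0], len(series)))
    for m, row in enumerate(pooled):
        theta = ThetaParams.from_array(row)
        try:
            res = filter_smoother(series, theta, init_probs)
            out[m] = res.smoothed[:, 0]
        except FilterError:
            out[m] = np.nan
    return out


def classify_windows(prob_draws: np.ndarray, prob_threshold: float = 0.5,
                     frac_threshold: float = 0.95) -> np.ndarray:
    """Three-way labels from the per-draw probability matrix."""
    prob_draws = np.asarray(prob_draws, dtype=float)
    if prob_draws.size == 0:
        raise ValueError("empty probability matrix")
    valid = ~np.isnan(prob_draws).any(axis=1)
    pd_ok = prob_draws[valid]
    frac_r1 = (pd_ok > prob_threshold).mean(axis=0)
    frac_r2 = (pd_ok < prob_threshold).mean(axis=0)
    labels = np.full(prob_draws.shape[1], "gray", dtype=object)
    labels[frac_r1 > frac_threshold] = "regime1"
    labels[frac_r2 > frac_threshold] = "regime2"
    return labels


def _paths_for_theta(theta_row: np.ndarray, m_edges: np.ndarray,
                     prob_r1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    npot, kappa = theta_row[0], theta_row[1]
    if npot <= 1:
        raise ValueError("draw with n_potential <= 1")
    np_branch1 = model.invert_population(m_edges, kappa)
    kappa_branch2 = model.invert_activity(m_edges, npot)
    np_t = prob_r1 * np_branch1 + (1.0 - prob_r1) * npot
    kappa_t = prob_r1 * kappa + (1.0 - prob_r1) * kappa_branch2
    return np_t, kappa_t


def parameter_paths(samples: PosteriorSamples, series: SnapshotSeries,
                    prob_draws: np.ndarray,
                    theta_hat: ThetaParams | None = None) -> ParameterPaths:
    """Point paths at the posterior-mean theta; bands from per-draw paths."""
    if theta_hat is None:
        theta_hat = samples.posterior_mean()
    m = series.m_edges.astype(float)
    prob_point = np.nanmean(prob_draws, axis=0)
    np_hat, kappa_hat = _paths_for_theta(theta_hat.as_array(), m, prob_point)
    pooled = samples.pooled()[: prob_draws.shape[0]]
    np_all = np.empty((prob_draws.shape[0], len(series)))
    ka_all = np.empty_like(np_all)
    for i, (row, probs) in enumerate(zip(pooled, prob_draws)):
        if np.isnan(probs).any() or row[0] <= 1:
            np_all[i] = np.nan
            ka_all[i] = np.nan
            continue
        np_all[i], ka_all[i] = _paths_for_theta(row, m, probs)
    np_lo, np_hi = np.nanpercentile(np_all, [2.5, 97.5], axis=0)
    ka_lo, ka_hi = np.nanpercentile(ka_all, [2.5, 97.5], axis=0)
    return ParameterPaths(
        np_hat=np_hat, np_lo=np_lo, np_hi=np_hi,
        kappa_hat=kappa_hat, kappa_lo=ka_lo, kappa_hi=ka_hi,
    )


def classify_series(samples: PosteriorSamples, series: SnapshotSeries,
                    init_probs=None, thin: int = 1, prob_threshold: float = 0.5,
                    frac_threshold: float = 0.95) -> RegimeClassification:
    """Smoothed-probability draws plus three-way labels in one call."""
    prob_draws = smoothed_prob_draws(samples, series, init_probs, thin=thin)
    labels = classify_windows(prob_draws, prob_threshold, frac_threshold)
    return RegimeClassification(
        labels=labels, prob_draws=prob_draws,
        prob_threshold=prob_threshold, frac_threshold=frac_threshold,
    )


def density_report(series: SnapshotSeries, labels: np.ndarray) -> pd.DataFrame:
    """Observed density 2M/(N(N-1)) per window alongside the regime label.

    Windows with N <= 1 have no defined density and get NaN.
    """
    n = series.n_active.astype(float)
    m = series.m_edges.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(n > 1, 2.0 * m / (n * (n - 1.0)), np.nan)
    return pd.DataFrame(
        {
            "window_start": series.window_start,
            "N": series.n_active,
            "M": series.m_edges,
            "label": np.asarray(labels, dtype=object),
            "density": dens,
        }
    )


def classification_table(series: SnapshotSeries, prob_draws: np.ndarray,
                         classification: RegimeClassification,
                         paths: ParameterPaths) -> pd.DataFrame:
    """Joined per-window output table (the `classify`/`report` CLI payload)."""
    lo, hi = np.nanpercentile(prob_draws, [2.5, 97.5], axis=0)
    dens = density_report(series, classification.labels)["density"]
    return pd.DataFrame(
        {
            "window_start": series.window_start,
            "N": series.n_active,
            "M": series.m_edges,
            "prob_regime1_mean": np.nanmean(prob_draws, axis=0),
            "prob_ci_low": lo,
            "prob_ci_high": hi,
            "label": classification.labels,
            "np_hat": paths.np_hat,
            "np_lo": paths.np_lo,
            "np_hi": paths.np_hi,
            "kappa_hat": paths.kappa_hat,
            "kappa_lo": paths.kappa_lo,
            "kappa_hi": paths.kappa_hi,
            "density": dens,
        }
    )
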