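"""Bayesian estimation of the switching-model parameters.

Posterior is ``p(theta | {D_t}) ∝ L({D_t} | theta) p(theta)`` with the
likelihood from the Hamilton filter and independent priors:

* ``N_p ~ Uniform(N_max, 2 N_max)`` with ``N_max = max_t N_t`` of the series,
* ``kappa ~ Uniform(0, 1)``,
* ``p11, p22 ~ Beta(5, 1)``,
* ``sigma1, sigma2 ~ half-Cauchy(scale 2)`` (the positive half; the residual
  scales must be positive).

Sampling runs on an unconstrained transformed space (logit for kappa and the
stay probabilities, log for the sigmas, identity for ``N_p``) so a random-walk
kernel mixes reasonably; Jacobian terms are included so the chain targets the
posterior of the natural parameters.  Two backends are provided: an adaptive
random-walk Metropolis sampler (default) and the emcee ensemble sampler, used
to cross-check posterior means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import FilterError, ThetaParams, hamilton_filter
from .series import SnapshotSeries

__all__ = [
    "PriorSpec",
    "PosteriorSamples",
    "default_priors",
    "log_prior",
    "log_posterior",
    "run_mcmc",
    "posterior_summary",
]

PARAM_NAMES = ("n_potential", "kappa", "sigma1", "sigma2", "p11", "p22")


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters; ``np_low``/``np_high`` come from the fitted series."""

    np_low: float
    np_high: float
    p_beta_a: float = 5.0
    p_beta_b: float = 1.0
    sigma_scale: float = 2.0

    def __post_init__(self):
        if not (1 <= self.np_low < self.np_high):
            raise ValueError("need 1 <= np_low < np_high")


def default_priors(series: SnapshotSeries) -> PriorSpec:
    """Data-dependent default: N_p uniform on (N_max, 2 N_max)."""
    n_max = int(series.n_active.max())
    if n_max == 0:
        raise ValueError("series has no active windows; N_p prior undefined")
    return PriorSpec(np_low=float(n_max), np_high=2.0 * float(n_max))


def log_prior(theta: ThetaParams, priors: PriorSpec) -> float:
    """Log prior density; -inf outside the support."""
    t = theta
    if not (priors.np_low < t.n_potential < priors.np_high):
        return -np.inf
    if not (0 < t.kappa < 1):
        return -np.inf
    if t.sigma1 <= 0 or t.sigma2 <= 0:
        return -np.inf
    if not (0 < t.p11 < 1 and 0 < t.p22 < 1):
        return -np.inf
    lp = -np.log(priors.np_high - priors.np_low)  # uniform N_p
    # kappa uniform(0,1): density 1
    lp += stats.beta.logpdf(t.p11, priors.p_beta_a, priors.p_beta_b)
    lp += stats.beta.logpdf(t.p22, priors.p_beta_a, priors.p_beta_b)
    lp += stats.halfcauchy.logpdf(t.sigma1, scale=priors.sigma_scale)
    lp += stats.halfcauchy.logpdf(t.sigma2, scale=priors.sigma_scale)
    return float(lp)


def log_posterior(theta, series: SnapshotSeries | None, priors: PriorSpec,
                  init_probs=None) -> float:
    """Log posterior kernel; -inf for invalid theta or filter degeneracies.

    ``theta`` may be a ThetaParams or a length-6 array in PARAM_NAMES order.
    ``series=None`` (or an empty series) drops the likelihood term, leaving
    the prior — useful for prior-predictive checks.
    """
    if not isinstance(theta, ThetaParams):
        try:
            theta = ThetaParams.from_array(theta)
        except ValueError:
            return -np.inf
    lp = log_prior(theta, priors)
    if not np.isfinite(lp):
        return -np.inf
    if series is None or len(series) == 0:
        return lp
    try:
        ll = hamilton_filter(series, theta, init_probs).loglik
    except (FilterError, ValueError):
        return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    return lp + ll


# ---------------------------------------------------------------------------
# transformed space


def _to_unconstrained(x: np.ndarray, priors: PriorSpec) -> np.ndarray:
    npot, kappa, s1, s2, p11, p22 = x
    logit = lambda p: np.log(p) - np.log1p(-p)
    return np.array([npot, logit(kappa), np.log(s1), np.log(s2), logit(p11), logit(p22)])


def _from_unconstrained(z: np.ndarray) -> np.ndarray:
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    return np.array([z[0], expit(z[1]), np.exp(z[2]), np.exp(z[3]), expit(z[4]), expit(z[5])])


def _log_jacobian(z: np.ndarray) -> float:
    # d theta / d z: sigmoid'(z) = s(1-s) for logit coords, e^z for log coords
    out = 0.0
    for idx in (1, 4, 5):
        out += -np.logaddexp(0.0, -z[idx]) - np.logaddexp(0.0, z[idx])
    out += z[2] + z[3]
    return float(out)


def _log_post_z(z, series, priors, init_probs):
    x = _from_unconstrained(z)
    return log_posterior(x, series, priors, init_probs) + _log_jacobian(z)


@dataclass
class PosteriorSamples:
    """Kept MCMC draws of theta, shaped (n_chains, n_keep, 6)."""

    draws: np.ndarray
    seed: int
    priors: PriorSpec
    n_burn: int
    diagnostics: dict = field(default_factory=dict)
    param_names: tuple = PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_keep(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean(self) -> ThetaParams:
        return ThetaParams.from_array(self.pooled().mean(axis=0))


def _init_point(rng: np.random.Generator, priors: PriorSpec) -> np.ndarray:
    width = priors.np_high - priors.np_low
    npot = priors.np_low + width * rng.uniform(0.05, 0.95)
    kappa = rng.uniform(0.05, 0.95)
    sig = np.clip(np.abs(stats.halfcauchy.rvs(scale=priors.sigma_scale, size=2,
                                              random_state=rng)), 0.5, 25.0)
    p = np.clip(stats.beta.rvs(priors.p_beta_a, priors.p_beta_b, size=2,
                               random_state=rng), 0.55, 0.995)
    return np.array([npot, kappa, sig[0], sig[1], p[0], p[1]])


def _map_start(series, priors, init_probs, rng, n_starts: int = 12) -> np.ndarray:
    """Posterior mode in the transformed space, from the best of a few starts.

    Used only to initialise the chains; Nelder-Mead is adequate because the
    filter likelihood is cheap and the space is 6-dimensional.
    """
    from scipy import optimize

    starts = [_to_unconstrained(_init_point(rng, priors), priors) for _ in range(n_starts)]
    starts.sort(key=lambda z: -_log_post_z(z, series, priors, init_probs))
    best_z, best_lp = starts[0], -np.inf
    for z0 in starts[:3]:
        res = optimize.minimize(
            lambda z: -_log_post_z(z, series, priors, init_probs), z0,
            method="Nelder-Mead", options={"maxiter": 800, "xatol": 1e-4, "fatol": 1e-4},
        )
        if -res.fun > best_lp:
            best_lp, best_z = -res.fun, res.x
    return best_z


def _rwm_chain(series, priors, init_probs, n_burn, n_keep, rng, z0):
    """Adaptive random-walk Metropolis; covariance adapted during burn-in only."""
    d = 6
    z = z0.copy()
    lp = _log_post_z(z, series, priors, init_probs)
    tries = 0
    while not np.isfinite(lp):
        z = _to_unconstrained(_init_point(rng, priors), priors)
        lp = _log_post_z(z, series, priors, init_probs)
        tries += 1
        if tries > 100:
            raise RuntimeError("could not find a valid starting point")
    log_scale = np.log(2.38 / np.sqrt(d))
    chol = np.diag([1.0, 0.2, 0.2, 0.2, 0.4, 0.4])
    total = n_burn + n_keep
    history = np.empty((total, d))
    kept = np.empty((n_keep, d))
    kept_accept = 0
    target = 0.234
    for it in range(total):
        prop = z + np.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = _log_post_z(prop, series, priors, init_probs)
        alpha = min(1.0, np.exp(min(0.0, lp_prop - lp)))
        if rng.random() < alpha:
            z, lp = prop, lp_prop
            if it >= n_burn:
                kept_accept += 1
        history[it] = z
        # diminishing adaptation: Robbins-Monro step-size tuning every
        # iteration, Haario-style covariance re-estimation from the later
        # half of the history every 100 iterations
        log_scale += min(0.1, 2.0 * (it + 1) ** -0.6) * (alpha - target)
        if it >= 300 and it % 100 == 0:
            emp = np.cov(history[it // 2: it].T) + 1e-8 * np.eye(d)
            try:
                chol = np.linalg.cholesky(emp)
            except np.linalg.LinAlgError:
                pass
        if it >= n_burn:
            kept[it - n_burn] = _from_unconstrained(z)
    return kept, kept_accept / max(1, n_keep)


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Rank-normalised split-R-hat per parameter via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(chains))
    return np.array([float(rhat["x"].values[i]) for i in range(chains.shape[-1])])


def run_mcmc(series: SnapshotSeries | None, priors: PriorSpec | None = None, *,
             n_chains: int = 4, n_keep: int = 5000, n_burn: int = 5000,
             seed: int = 0, init_probs=None, backend: str = "rwm",
             rhat_threshold: float = 1.05) -> PosteriorSamples:
    """Sample the posterior of theta.

    Defaults mirror a full run (4 chains, 5,000 kept after 5,000 burn-in each);
    scale ``n_keep``/``n_burn`` down for quick exploration.  ``backend`` is
    ``"rwm"`` (adaptive random-walk Metropolis) or ``"emcee"`` (affine-invariant
    ensemble).  Identical seeds give identical draws.
    """
    if priors is None:
        if series is None:
            raise ValueError("need explicit priors when no series is given")
        priors = default_priors(series)
    master = np.random.SeedSequence(seed)
    jitter = np.array([0.5, 0.1, 0.1, 0.1, 0.2, 0.2])
    if backend == "rwm":
        pilot_rng = np.random.default_rng(master.spawn(1)[0])
        if series is not None and len(series) > 0:
            z_map = _map_start(series, priors, init_probs, pilot_rng)
        else:
            z_map = _to_unconstrained(_init_point(pilot_rng, priors), priors)
        chains = []
        rates = []
        for child in master.spawn(n_chains):
            rng = np.random.default_rng(child)
            z0 = z_map + jitter * rng.standard_normal(6)
            kept, rate = _rwm_chain(series, priors, init_probs, n_burn, n_keep, rng, z0)
            chains.append(kept)
            rates.append(rate)
        draws = np.stack(chains)
        diag = {"accept_rate": np.asarray(rates)}
    elif backend == "emcee":
        import emcee

        n_walkers = max(16, 4 * n_chains)
        rng = np.random.default_rng(master)
        if series is not None and len(series) > 0:
            z_map = _map_start(series, priors, init_probs, rng)
            p0 = z_map + jitter * rng.standard_normal((n_walkers, 6))
        else:
            p0 = np.stack([
                _to_unconstrained(_init_point(rng, priors), priors)
                for _ in range(n_walkers)
            ])
        sampler = emcee.EnsembleSampler(
            n_walkers, 6, _log_post_z, args=(series, priors, init_probs)
        )
        n_steps = n_burn + n_keep
        sampler.random_state = np.random.RandomState(
            int(master.generate_state(1)[0]) % (2 ** 32 - 1)
        ).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        z = sampler.get_chain(discard=n_burn)  # (n_keep, n_walkers, 6)
        natural = np.apply_along_axis(_from_unconstrained, -1, z)
        draws = natural.transpose(1, 0, 2)  # walkers as chains
        diag = {"accept_rate": sampler.acceptance_fraction}
    else:
        raise ValueError(f"unknown backend {backend!r}")
    rhat = _split_rhat(draws)
    converged = bool(np.all(rhat < rhat_threshold))
    if not converged:
        warnings.warn(
            f"split-R-hat above {rhat_threshold} for "
            f"{[PARAM_NAMES[i] for i in np.where(rhat >= rhat_threshold)[0]]}",
            RuntimeWarning, stacklevel=2,
        )
    diag.update({"rhat": rhat, "converged": converged})
    return PosteriorSamples(draws=draws, seed=seed, priors=priors,
                            n_burn=n_burn, diagnostics=diag)


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Pooled mean and equal-tailed central 95% credible interval per parameter."""
    pooled = samples.pooled()
    if pooled.size == 0:
        raise ValueError("no draws to summarise")
    lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "parameter": list(samples.param_names),
            "mean": pooled.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
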