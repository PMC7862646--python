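# Methods

## The model

A temporal contact network is summarised window by window as D_t = (N_t, M_t):
the number of nodes with at least one contact and the number of distinct
contacted pairs in window t. The generative picture is a dynamic
hidden-variable graph: at time t there are N_p,t *potential* individuals
(present, but possibly isolated), each with an intrinsic activity
a_i ~ Uniform[0, 1], and every unordered pair is connected independently with
probability kappa_t * a_i * a_j. N_p,t is latent — people without contacts
leave no trace in the data — and kappa_t is a global modulator of the contact
propensity (schedules, breaks, working hours).

Averaging over the activity distribution gives exact moments:

    M  = kappa * N_p * (N_p - 1) / 8
    q0 = (2 / (kappa * N_p)) * (1 - (1 - kappa/2)^N_p)     (isolated fraction)
    N  = (1 - q0) * N_p
    kbar = kappa * (N_p - 1) / 4 = 2 M / N_p               (mean degree, all nodes)

and the density identity

    2M / (N(N-1)) = (kappa/4) * (1 - q0)^{-2} * (1 + q0/(N-1)),

which tends to kappa/4 from above as N_p grows at fixed kappa, and is
unbounded when kappa grows at fixed N_p — the two mechanisms leave different
fingerprints in the (N, M) plane. Eliminating one parameter through the M
equation yields the two regime curves h1(M; kappa) (population-driven) and
h2(M; N_p) (activity-driven) and the exact inverse maps

    N_p(M, kappa) = (1 + sqrt(1 + 32 M / kappa)) / 2
    kappa(M, N_p) = 8 M / (N_p (N_p - 1)).

Assumptions worth keeping in mind: homogeneous mixing (no triadic closure,
communities or homophily), uniform activities (a general activity density
breaks the closed forms), and independence of snapshots given the latent
parameters.

## Switching observation model and exact inference

The hidden regime S_t ∈ {1, 2} follows a first-order Markov chain with stay
probabilities p11, p22. Given S_t = s, the observed N_t is Gaussian around
the corresponding curve at the observed M_t with regime-specific residual
standard deviation sigma_s (in units of individuals). The constant parameter
vector is theta = {N_p, kappa, sigma1, sigma2, p11, p22}; the time-varying
N_p,t and kappa_t are *not* sampled — they are reconstructed after the fact
from the inverse maps.

The Hamilton filter propagates Pr(S_t | D_1..t) and accumulates the exact
log-likelihood; the Kim smoother runs the standard backward fixed-interval
recursion xi_{t|T} = xi_{t|t} ⊙ P [xi_{t+1|T} ⊘ xi_{t+1|t}]. Both are
validated against exhaustive 2^T path enumeration (tests assert agreement to
1e-10 on random instances). The filter update is performed on max-rescaled
log densities so far-off observations cannot underflow; if both regime
densities vanish at a window the filter raises rather than propagating NaNs.

Conventions: the initial state distribution defaults to (0.5, 0.5) and is
interpreted as the *pre-sample* state, so one transition is applied before
the first observation (the stationary distribution of the chain is available
as an option). Windows with N_t = 0 are fitted like any other: h1(0) = 0, so
an all-quiet window is explained exactly by Regime 1.

Numerical notes: (1 - kappa/2)^N_p is computed as exp(N_p log(1 - kappa/2))
because N_p is real-valued throughout the inference (the inverse map returns
non-integers); only the simulator rounds. h2 requires the implied
kappa = 8M/(N_p(N_p-1)) to stay ≤ 2 (the real domain of the power); values in
(1, 2] are evaluated — physically inconsistent but needed while MCMC
proposals explore — and the Gaussian error term absorbs them, while values
> 2 raise a domain error that the posterior maps to -inf.

## Priors and posterior sampling

Priors follow standard weakly-informative practice for this model:
N_p ~ Uniform(N_max, 2 N_max) with N_max = max_t N_t (the potential
population can never be below the largest observed active count),
kappa ~ Uniform(0, 1), p11, p22 ~ Beta(5, 1) (favouring persistent regimes),
sigma1, sigma2 ~ half-Cauchy(scale 2) — the positive half, since the residual
scales must be positive.

The default sampler is an adaptive random-walk Metropolis on a transformed
space (logit for kappa and the stay probabilities, log for the sigmas,
identity for N_p, with Jacobian corrections): proposal covariance is
re-estimated every 100 iterations from the later half of the chain history
and the global step size follows a diminishing Robbins–Monro recursion
targeting 23.4% acceptance. Chains start in a jittered ball around the
posterior mode located by Nelder–Mead from the best of a dozen prior draws;
this avoids a slow-to-escape ridge where one regime's sigma inflates into a
catch-all. Convergence is reported per parameter as rank-normalised
split-R-hat (threshold 1.05) and surfaced as a warning, never silently.
The library default run size is 4 chains with 5,000 kept draws after 5,000
burn-in each; the test-suite and acceptance runs use 4 × (2,500 burn +
750 kept) = 3,000 kept draws, which the diagnostics show is enough for
stable posterior means at T = 200. The posterior has a long flat shelf in
(N_p, sigma2) — the regime-2 density flattens as sigma2 grows and the
half-Cauchy tail decays slowly — through which short chains mix slowly;
longer burn-in, not tighter priors, is the chosen remedy.

A second backend (emcee's affine-invariant ensemble, walkers reported as
chains) exists purely so the two sampling strategies can be cross-checked
against each other; tests assert their posterior means agree.

## Regime classification and parameter paths

For every kept draw theta^(m), the filter+smoother yields
Pr(S_t = 1 | psi_T; theta^(m)). A window is labelled regime 1 when more than
95% of draws put that probability above 0.5, regime 2 symmetrically, and
"gray" otherwise; both thresholds are configurable. Classification can be
thinned to every k-th draw for speed (recorded in the call, default none in
the library, thin=2 in the acceptance run).

Point paths use the pooled posterior mean theta-hat:

    Np_hat_t   = Pr(S_t=1) * (1 + sqrt(1 + 32 M_t / kappa_hat)) / 2 + Pr(S_t=2) * Np_hat
    kappa_hat_t = Pr(S_t=1) * kappa_hat + Pr(S_t=2) * 8 M_t / (Np_hat (Np_hat - 1))

and the 95% bands come from evaluating the same expressions per draw and
taking equal-tailed percentiles. Draws with N_p ≤ 1 (impossible under the
prior) would be flagged and excluded from bands.

## The synthetic-data generator

The simulator emulates regime-switching dynamics directly in the model's own
terms: a Markov state sequence (initial Regime-1 probability 0.5), a
geometric decay of the *active* latent parameter — N_p,t = 0.95 N_p,t-1 in
Regime-1 windows with kappa at its base, and symmetrically in Regime 2 —
with the inactive parameter reset to base, starting from the bases before
the first window. Each window is then realised as an actual random graph
(activities redrawn per window by default; a node-persistent mode exists),
so all combinatorial constraints (M ≤ N(N-1)/2, M ≥ N/2, N ≤ N_p) hold by
construction and ensemble means converge to the closed forms — both are
asserted in tests. Ground truth records the unrounded decayed paths; only
graph realisation rounds N_p,t to an integer.

Default study conditions (base N_p = 200, kappa = 0.3, p11 = p22 = 0.95,
decay 0.95, T = 200 windows, 600-s windows) correspond to a conference-scale
system with persistent regimes. What the generator does *not* emulate:
burstiness and circadian rhythm within windows, community structure,
activity heterogeneity beyond Uniform[0,1], and participant turnover — so
passing recovery tests demonstrates correctness of the inference under the
model's own assumptions, not robustness to their violation on real data.

The generator can emit its run as a SocioPatterns-style tij event file (each
window's edges written once at the window start); re-windowing that file
must reproduce the (N_t, M_t) series exactly, which is tested and reported
by the acceptance script.

## Windowing real contact data

tij input is whitespace-separated `t i j` text (gzip accepted), timestamps
in seconds; identifiers are opaque strings. Windows are half-open
[origin + k·w, origin + (k+1)·w) with w = 600 s by default and the origin
anchored at the first event floored to a multiple of w. An edge requires at
least one event in the window (a `min_events` option exists); repeated
events of a pair collapse to one edge. Empty windows are dropped by default
— overnight gaps would otherwise produce long (0, 0) runs that the Gaussian
observation model has no business fitting; `drop_empty=False` keeps them.

## Design choices and limitations

- Exactly two regimes; mixed windows surface as intermediate probabilities
  and gray labels, not as a third state.
- N_p is continuous in all inference code; the likelihood evaluates the
  curves at real N_p.
- `invert_activity` never clamps: physically inconsistent implied kappa > 1
  is returned raw and the caller (or the error model) decides.
- Posterior summaries pool chains; credible intervals are equal-tailed.
- Problem sizes in the test suite (T = 200 recovery, 3,000 kept draws,
  10,000-replicate moment checks) are scaled-down replicas of a full
  analysis chosen so the whole suite runs in a few minutes on one CPU;
  the library defaults remain full-size.
- For a system known to be in a single fixed regime the switching machinery
  is unnecessary — fit each curve separately instead; this package targets
  systems whose driving mechanism may change over time.
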