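"""Closed-form moments of the hidden-variable snapshot model.

For a potential population N_p with Uniform[0,1] activities and pair
connection probability kappa*a_i*a_j, print the expected snapshot summary
statistics and show the exact inverse maps used by the two regime curves.
"""

import densiswitch as ds
from densiswitch import model

kappa, n_p = 0.3, 126

m = model.expected_edges(kappa, n_p)
n = model.expected_active_nodes(kappa, n_p)
q0 = model.isolated_fraction(kappa, n_p)
kbar = model.mean_degree(kappa, n_p)
dens = model.expected_density(kappa, n_p)

print(f"kappa={kappa}, N_p={n_p}")
print(f"  expected edges          M    = {m:.3f}")
print(f"  expected active nodes   N    = {n:.3f}")
print(f"  isolated fraction       q0   = {q0:.4f}")
print(f"  mean degree (all nodes) kbar = {kbar:.4f}")
print(f"  expected density 2M/(N(N-1)) = {dens:.4f}  (-> kappa/4 = {kappa/4} as N_p grows)")

# The inverse maps recover the latent parameter from an observed edge count.
print(f"  invert_population(M, kappa)  = {model.invert_population(m, kappa):.3f}  (== N_p)")
print(f"  invert_activity(M, N_p)      = {model.invert_activity(m, n_p):.3f}  (== kappa)")

# Regime curves: expected N for an observed M under each driving mechanism.
for m_obs in (100.0, 300.0, 590.625):
    h1 = model.regime1_curve(m_obs, kappa)
    h2 = model.regime2_curve(m_obs, n_p)
    print(f"  M={m_obs:8.1f}: population-driven N={h1:7.2f}   activity-driven N={h2:7.2f}")
print("Where the two curves give different N for the same M, the regimes are"
      " distinguishable from (N, M) data alone.")
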