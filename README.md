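# densiswitch

Why does a social contact network get denser or sparser over time? Window by
window, any change in the number of active nodes *N* and edges *M* of a
temporal network comes from two fundamental mechanisms: people entering or
leaving the system (a change in the **potential population** N<sub>p</sub>,
which includes currently isolated individuals), or a change in the chance
that people present actually interact (an **overall activity** level κ).
`densiswitch` takes a per-window series of (N<sub>t</sub>, M<sub>t</sub>)
counts — typically aggregated from SocioPatterns-style RFID contact data in
10-minute snapshots — and infers, for every window, which mechanism is
driving the dynamics, together with the latent paths of N<sub>p,t</sub> and
κ<sub>t</sub>.

## Model

Each snapshot is a hidden-variable (fitness) random graph over
N<sub>p</sub> nodes: node *i* carries an activity a<sub>i</sub> ~
Uniform[0, 1] and each pair connects independently with probability
κ·a<sub>i</sub>a<sub>j</sub>. Averaging over activities gives closed forms

- M = κ N<sub>p</sub>(N<sub>p</sub> − 1)/8,
- N = N<sub>p</sub>[1 − q₀], with isolated fraction
  q₀ = (2/κN<sub>p</sub>)[1 − (1 − κ/2)^{N<sub>p</sub>}].

Eliminating one parameter yields two one-dimensional scaling curves in the
(M, N) plane:

- **Regime 1** (population-driven): κ fixed, N<sub>p</sub> varies —
  N = h¹(M; κ), a near-constant-slope densification scaling;
- **Regime 2** (activity-driven): N<sub>p</sub> fixed, κ varies —
  N = h²(M; N<sub>p</sub>), an accelerating ("explosive") growth of M with N.

A two-state Markov chain with stay probabilities p₁₁, p₂₂ switches the
system between the regimes; observed N<sub>t</sub> is Gaussian around the
active curve with regime-specific residual scale σ₁ or σ₂. The Hamilton
filter gives the exact likelihood of θ = {N<sub>p</sub>, κ, σ₁, σ₂, p₁₁,
p₂₂}; the Kim smoother gives Pr(S<sub>t</sub> = s | whole series). The
posterior of θ (uniform, Beta(5,1) and half-Cauchy priors) is sampled by
MCMC; each draw induces smoothed regime probabilities, and a window is
labelled regime 1 (resp. 2) when more than 95% of draws put that probability
above (below) 0.5 — otherwise it falls in an undetermined "gray area".

## Worked example

`examples/03_fit_and_classify.py` simulates 80 windows with known regimes
(N<sub>p</sub> = 100, κ = 0.4, p₁₁ = p₂₂ = 0.9, 5% per-window decay of the
active parameter), fits the model and classifies every window. It prints:

```
  parameter    mean  ci_low  ci_high
n_potential 99.4725 98.3716 100.8145
      kappa  0.3919  0.3748   0.4123
     sigma1  4.6053  3.6119   6.0623
     sigma2  3.1115  2.5300   3.8748
        p11  0.9424  0.8427   0.9939
        p22  0.9455  0.8749   0.9867
truth: N_p=100, kappa=0.4, p11=p22=0.9

labels: {'regime1': 33, 'regime2': 45, 'gray': 2}
accuracy on non-gray windows: 96.2%
```

The posterior means sit on the generating values (the 95% credible
intervals cover all four constants), and 75 of the 78 confidently labelled
windows get the true driving mechanism. The other examples cover the closed
forms (`01`), the generative simulator (`02`) and windowing raw contact
events (`04`).

## Command line

The same workflow is scriptable:

```sh
densiswitch --seed 4 simulate --n-windows 200 --out series.csv --truth-out truth.csv
densiswitch window contacts.tij --width 600 --out series.csv   # from real tij data
densiswitch --seed 4 fit series.csv --summary-out summary.csv --draws-out draws.csv
densiswitch classify series.csv draws.csv --out windows.csv
densiswitch report windows.csv
```

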